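import numpy as np
import pytest

import uprfate as uf


@pytest.fixture(scope="session")
def params():
    return uf.DEFAULT_PARAMS


@pytest.fixture(scope="session")
def default_curve():
    """Signal-response curve of the shipped default set, reused across tests."""
    return uf.signal_response(uf.DEFAULT_PARAMS, n_points=241)


@pytest.fixture(scope="session")
def siperk_curve():
    return uf.signal_response(uf.preset("siPERK"), n_points=241)


@pytest.fixture(scope="session")
def ire1_curve():
    return uf.signal_response(uf.preset("IRE1-inhibited"), n_points=241)


@pytest.fixture(scope="session")
def high_stress_traj():
    return uf.run_scenario("high_stress")


@pytest.fixture(scope="session")
def low_stress_traj():
    return uf.run_scenario("low_stress")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
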