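"""Scenario integration: fixed points, basins, ordering and wash-out."""
import numpy as np
import pytest

import uprfate as uf
from uprfate.phenotype import extract_features
from uprfate.protocols import Protocol


def test_zero_stress_from_origin_stays_at_origin(params):
    traj = uf.integrate(params, Protocol(schedule=((0.0, 0.0),), horizon=20.0))
    assert np.max(np.abs(traj.states)) == 0.0
    assert traj.settled


def test_invalid_protocols_rejected():
    with pytest.raises(ValueError):
        Protocol(schedule=((0.0, 25.0), (0.0, 0.0)))   # non-increasing times
    with pytest.raises(ValueError):
        Protocol(schedule=((1.0, 25.0),))               # must start at 0
    with pytest.raises(ValueError):
        Protocol(horizon=-1.0)
    with pytest.raises(ValueError):
        Protocol(dt=0.0)


def test_unknown_scenario_raises(params):
    with pytest.raises(KeyError):
        uf.run_scenario("mild_stress", params)


@pytest.mark.parametrize("stress,branch", [(25.0, "low"), (40.0, "high")])
def test_final_state_lands_on_predicted_branch(params, stress, branch):
    """Scenario endpoints agree with the steady-state finder to 1e-3."""
    traj = uf.run_scenario("low_stress" if stress == 25 else "high_stress", params)
    assert traj.settled
    half = 0.5 * params.AT_apop
    want = [s for s in uf.find_steady_states(params, stress)
            if s.stable and ((s.apop < half) == (branch == "low"))]
    assert len(want) == 1
    assert abs(traj.series("apop")[-1] - want[0].apop) < 1e-3


def test_high_stress_survival_window_precedes_death(high_stress_traj, params):
    """The autophagy peak comes before the apoptosis half-activation."""
    auto = high_stress_traj.series("auto")
    apop = high_stress_traj.series("apop")
    t = high_stress_traj.time
    t_peak = t[np.argmax(auto)]
    onset = extract_features(t, apop, scale=params.AT_apop).onset
    assert onset is not None
    assert t_peak < onset
    # death wins and excludes autophagy at the end
    assert apop[-1] > 0.5 * params.AT_apop
    assert auto[-1] < 0.5 * params.AT_auto


def test_steady_states_are_mutually_exclusive(low_stress_traj, high_stress_traj, params):
    """The two inducers never both sit above half-total at the end state."""
    for traj in (low_stress_traj, high_stress_traj):
        assert not (traj.series("auto")[-1] > 0.5 * params.AT_auto
                    and traj.series("apop")[-1] > 0.5 * params.AT_apop)


def test_siperk_never_commits_and_keeps_autophagy_high(params):
    traj = uf.run_scenario("siPERK_high_stress", params)
    assert np.max(traj.series("apop")) < 0.5 * params.AT_apop
    assert traj.series("auto")[-1] > 0.5 * params.AT_auto


def test_knockdown_onset_shifts(high_stress_traj, params):
    """siPERK delays (here: abolishes) death; IRE-1 loss brings it forward."""
    t = high_stress_traj.time
    ref = extract_features(t, high_stress_traj.series("apop"), scale=params.AT_apop).onset
    il = uf.run_scenario("IRE1low_high_stress", params)
    early = extract_features(il.time, il.series("apop"), scale=params.AT_apop).onset
    sp = uf.run_scenario("siPERK_high_stress", params)
    late = extract_features(sp.time, sp.series("apop"), scale=params.AT_apop).onset
    assert early is not None and early < ref
    assert late is None or late > ref


def test_washout_after_commitment_is_point_of_no_return(params):
    """Removing the stressor after commitment leaves the death switch on."""
    traj = uf.run_scenario("washout", params)
    assert len(traj.events) == 1
    wash_t = traj.events[0]
    assert wash_t > uf.commitment_time(params)
    post = traj.series("apop")[traj.time > wash_t]
    assert post[-1] > 0.9 * params.AT_apop
    # stress really was removed
    assert traj.stress[-1] == 0.0


def test_stress_step_changes_are_marked_and_respected(params):
    proto = Protocol(schedule=((0.0, 40.0), (10.0, 5.0)), horizon=20.0)
    traj = uf.integrate(params, proto)
    assert traj.events == (10.0,)
    assert traj.stress[traj.time <= 9.9].max() == 40.0
    assert traj.stress[traj.time > 10.0].max() == 5.0


def test_trajectory_tidy_frame_layout(high_stress_traj):
    df = high_stress_traj.to_frame()
    assert set(df.columns) == {"time", "variable", "value", "scenario"}
    assert set(df["variable"]) == {"perk", "ire1", "auto", "apop"}
    assert (df["scenario"] == "high_stress").all()
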