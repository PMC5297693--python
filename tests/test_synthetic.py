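"""Synthetic densitometry generator and phenotype-recovery study."""
import numpy as np
import pytest

import uprfate as uf
from uprfate.phenotype import MARKER_MAP
from uprfate.synthetic import classify_timecourse


def test_noise_free_samples_equal_normalised_trajectory(params):
    reps = uf.generate_timecourse(params, "high_stress", cv=0.0, n_replicates=2, seed=3)
    traj = uf.run_scenario("high_stress", params)
    for marker, vals in reps[0].intensities.items():
        var = next(v for v, ms in MARKER_MAP.items() if marker in ms)
        ref = np.interp(reps[0].time, traj.time, traj.series(var))
        ref = ref / ref.max()
        assert np.allclose(vals, ref)
    # replicates are identical when noiseless
    for m in reps[0].intensities:
        assert np.array_equal(reps[0].intensities[m], reps[1].intensities[m])


def test_same_seed_reproduces_noise_exactly(params):
    a = uf.generate_timecourse(params, "low_stress", cv=0.2, seed=7)
    b = uf.generate_timecourse(params, "low_stress", cv=0.2, seed=7)
    for ra, rb in zip(a, b):
        for m in ra.intensities:
            assert np.array_equal(ra.intensities[m], rb.intensities[m])


def test_replicates_use_independent_noise(params):
    reps = uf.generate_timecourse(params, "low_stress", cv=0.2, seed=7)
    assert not np.array_equal(reps[0].intensities["CHOP"], reps[1].intensities["CHOP"])


def test_default_design_is_three_replicates(params):
    reps = uf.generate_timecourse(params, "high_stress", seed=0)
    assert len(reps) == 3
    assert all(np.all(r.intensities[m] >= 0) for r in reps for m in r.intensities)


def test_empirical_cv_matches_requested(params):
    """Monte-Carlo check of the lognormal noise: per-sample CV within 10 %."""
    cv = 0.2
    reps = uf.generate_timecourse(params, "high_stress", cv=cv,
                                  n_replicates=500, seed=11)
    stack = np.stack([r.intensities["CHOP"] for r in reps])
    keep = stack.mean(axis=0) > 0.2  # avoid ratio noise at near-zero baseline
    emp = stack.std(axis=0, ddof=1)[keep] / stack.mean(axis=0)[keep]
    assert abs(np.median(emp) - cv) < 0.1 * cv


def test_oversized_sampling_interval_rejected(params):
    with pytest.raises(ValueError):
        uf.generate_timecourse(params, "high_stress", sampling_interval=1e4)
    with pytest.raises(ValueError):
        uf.generate_timecourse(params, cv=-0.1)
    with pytest.raises(ValueError):
        uf.generate_timecourse(params, n_replicates=0)


def test_minutes_axis_places_death_switch_in_blot_range(params):
    """Cosmetic minute labels put the high-stress commitment in the 60-180
    min range typical of the blot panels."""
    reps = uf.generate_timecourse(params, "high_stress", cv=0.0, n_replicates=1, seed=0)
    tc = reps[0]
    pooled = np.mean([tc.intensities[m] for m in MARKER_MAP["apop"]], axis=0)
    onset_min = tc.minutes[np.argmax(pooled > 0.5)]
    assert 30.0 <= onset_min <= 240.0


@pytest.fixture(scope="module")
def recovery():
    return uf.recovery_study(n_replicates=200, cv_grid=(0.0, 0.05, 0.1, 0.2), seed=0)


def test_recovery_is_perfect_without_noise(recovery):
    assert (recovery.loc[recovery.cv == 0.0, "recovery"] == 1.0).all()


def test_recovery_at_cv01_meets_frozen_threshold(recovery):
    """Frozen regression: noisy phenotype recovery at cv = 0.1."""
    r = recovery.loc[recovery.cv == 0.1]
    assert (r["recovery"] >= 0.95).all()


def test_recovery_never_increases_with_noise(recovery):
    """Monotone in cv up to Monte-Carlo tolerance 0.02."""
    for scen, grp in recovery.groupby("scenario"):
        vals = grp.sort_values("cv")["recovery"].to_numpy()
        assert np.all(np.diff(vals) <= 0.02)


def test_noiseless_calls_match_the_biology(recovery):
    truth = dict(recovery.groupby("scenario")["noiseless_phenotype"].first())
    assert truth["low_stress"] == "survival"
    assert truth["high_stress"] == "death"
    assert truth["siPERK_high_stress"] == "survival"
    assert truth["IRE1low_high_stress"] == "death"


def test_marker_mode_classification_consistent_with_trajectory(params):
    """A clean marker panel and the underlying trajectory give the same call."""
    clean = uf.generate_timecourse(params, "low_stress", cv=0.0, n_replicates=1, seed=0)[0]
    assert classify_timecourse(clean, None).phenotype == "survival"
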