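"""Steady-state finder, signal-response branches, folds and reversibility."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

import uprfate as uf
from uprfate.model import rhs


def test_zero_stress_equilibria_include_unstable_origin(params):
    """With the sensor loop self-sustaining, the resting state coexists with
    the survival and death attractors at zero stress — the structural basis
    of the point of no return."""
    states = uf.find_steady_states(params, 0.0)
    origin = [s for s in states if np.max(np.abs(s.state)) < 1e-9]
    assert len(origin) == 1 and not origin[0].stable
    stable = [s for s in states if s.stable]
    assert len(stable) == 2
    apops = sorted(s.apop for s in stable)
    assert apops[0] < 0.5 < apops[1]


def test_two_stable_one_unstable_inside_window(params, default_curve):
    """Between the folds: exactly two attractors separated by a saddle."""
    lo = 0.5  # strictly inside (sn_off below scan, sn_on ~ 37)
    hi = default_curve.sn_on - 0.5
    for S in np.linspace(lo, hi, 5):
        states = uf.find_steady_states(params, S)
        assert sum(s.stable for s in states) == 2
        assert sum(not s.stable for s in states) >= 1


def test_steady_states_match_relaxation_oracle(params):
    """Root finding agrees with brute-force multi-start integration to 1e-6
    below, inside and above the bistable window."""
    for S in (10.0, 25.0, 50.0):
        stable = [s.state for s in uf.find_steady_states(params, S) if s.stable]
        clusters = uf.steady_states_by_relaxation(params, S)
        assert len(clusters) == len(stable)
        for c in clusters:
            assert min(np.max(np.abs(c - r)) for r in stable) < 1e-6


def test_stability_flags_verified_by_perturbation(params):
    """1e-3 perturbations relax back to stable points; states near the saddle
    diverge to one of the two attractors."""
    S = 25.0
    p = params.with_stress(S)
    states = uf.find_steady_states(params, S)
    stable = [s for s in states if s.stable]
    saddle = [s for s in states if not s.stable][0]
    f = lambda t, y: rhs(y, p)
    for s in stable:
        y0 = np.clip(s.state + 1e-3, 0, None)
        sol = solve_ivp(f, (0, 200), y0, method="LSODA", rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(sol.y[:, -1] - s.state)) < 1e-6
    for eps in (+1e-3, -1e-3):
        y0 = np.clip(saddle.state + np.array([0, 0, 0, eps]), 0, None)
        sol = solve_ivp(f, (0, 400), y0, method="LSODA", rtol=1e-10, atol=1e-12)
        dist = min(np.max(np.abs(sol.y[:, -1] - s.state)) for s in stable)
        assert dist < 1e-6  # left the saddle for an attractor


def test_default_curve_shape_and_folds(default_curve):
    """Low branch at small stress, high branch at large stress, unstable
    branch in between; activation fold between the printed scenario levels."""
    assert default_curve.bistable
    assert default_curve.max_coexisting_stable() == 2
    assert default_curve.sn_on_status == "found"
    assert 25.0 < default_curve.sn_on < 40.0
    assert default_curve.sn_off_status == "below_scan"
    first, last = default_curve.points[0], default_curve.points[-1]
    assert any(s.stable and s.apop < 0.5 for s in first)
    assert all(s.apop > 0.5 for s in last if s.stable)
    # unstable saddle present inside the window
    mid = default_curve.points[len(default_curve.stress) // 3]
    assert any(not s.stable for s in mid)


def test_no_feedback_means_no_folds(params):
    curve = uf.signal_response(params.replace(k_x_aa=0.0, k_x_apa=0.0),
                               n_points=121)
    assert not curve.bistable
    assert curve.sn_on_status in ("none", "above_scan")
    assert uf.classify_reversibility(curve) == "no_switch"


def test_reversibility_classification(default_curve, siperk_curve, ire1_curve):
    assert uf.classify_reversibility(default_curve) == "irreversible"
    assert uf.classify_reversibility(siperk_curve) == "reversible"
    assert uf.classify_reversibility(ire1_curve) == "reversible"
    assert siperk_curve.sn_off > 0
    assert ire1_curve.sn_off > 0


def test_threshold_shifts_have_the_reported_signs(default_curve, siperk_curve, ire1_curve):
    """PERK knockdown shifts activation right (beyond stress 40); IRE-1
    knockdown shifts it left."""
    d_sp = uf.threshold_shift(default_curve, siperk_curve)
    d_il = uf.threshold_shift(default_curve, ire1_curve)
    assert d_sp > 0
    assert np.isinf(d_sp) or default_curve.sn_on + d_sp > 40.0
    assert d_il < 0
    assert uf.threshold_shift(default_curve, default_curve) == 0.0


def test_branch_assembly_labels_are_consistent(default_curve):
    """Continuation assigns each column's states to continuing branches."""
    ids = default_curve.branch_ids
    assert len(ids) == len(default_curve.stress)
    # the high branch exists throughout the scan: one id spans every column
    spanning = set(ids[0])
    for col in ids:
        spanning &= set(col)
    assert spanning


def test_hysteresis_ramp_matches_folds(params, default_curve, ire1_curve):
    """Slow time-domain ramps jump within 2 scan steps (0.2 stress units at
    the 600-point default resolution) of the curve folds — and never jump
    down for the irreversible default."""
    tol = 0.2
    h = uf.hysteresis_ramp(params)
    assert abs(h["jump_up_stress"] - default_curve.sn_on) <= tol
    assert h["jump_down_stress"] is None
    il = uf.preset("IRE1-inhibited", params)
    h2 = uf.hysteresis_ramp(il)
    assert abs(h2["jump_up_stress"] - ire1_curve.sn_on) <= tol
    assert abs(h2["jump_down_stress"] - ire1_curve.sn_off) <= tol


def test_curve_frame_layout(default_curve):
    df = default_curve.to_frame()
    assert {"stress", "apop", "stability", "branch_id"} <= set(df.columns)
    assert set(df["stability"]) == {"stable", "unstable"}
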