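"""Steady states, stability, signal-response curves and fold (saddle-node) points.

The model's structure makes an exhaustive equilibrium search cheap and
reliable: the sensor pair (perk, ire1) is an autonomous subsystem whose
nullclines compose into a concave 1-D fixed-point problem (unique positive
solution for stress > 0; at stress 0 the origin plus, when the positive
feedback loop is self-sustaining, one positive state).  Given sensor levels,
each inducer nullcline is exactly quadratic in its own variable, so every
equilibrium of the 2-D toggle is found by following the quadratic branches of
one nullcline and bracketing sign changes of the other.  No random
multi-starts are involved; a brute-force relaxation oracle is provided
separately for cross-checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import jacobian, rhs
from .params import ParameterSet

__all__ = [
    "SteadyState",
    "SignalResponseCurve",
    "find_steady_states",
    "steady_states_by_relaxation",
    "signal_response",
    "classify_reversibility",
    "threshold_shift",
    "hysteresis_ramp",
]

#: deduplication tolerance (max norm) and stability margin on Re(lambda)
DEDUP_TOL = 1e-6
STABILITY_MARGIN = -1e-9


@dataclass(frozen=True)
class SteadyState:
    state: np.ndarray
    stable: bool
    max_re_eig: float

    @property
    def apop(self) -> float:
        return float(self.state[3])


# -- sensor subsystem -------------------------------------------------------

def _sensor_states(p: ParameterSet, S: float) -> list[tuple[float, float]]:
    """All equilibria (perk, ire1) of the autonomous sensor pair at stress S."""
    def P_of(I):
        a = p.k_sp * S + p.k_ip * I
        return a * p.PERKT / (a + p.k_dp) if a + p.k_dp > 0 else 0.0

    def I_of(P):
        a = p.k_si * S + p.k_pi * P
        return a * p.IRE1T / (a + p.k_di) if a + p.k_di > 0 else 0.0

    g = lambda P: P_of(I_of(P)) - P
    out: list[tuple[float, float]] = []
    if S <= 0:
        out.append((0.0, 0.0))
        # self-sustained state exists iff the loop gain at the origin exceeds 1
        if p.k_dp > 0 and p.k_di > 0:
            gain = (p.k_ip * p.IRE1T / p.k_di) * (p.k_pi * p.PERKT / p.k_dp)
        else:
            gain = np.inf if p.k_ip * p.k_pi > 0 else 0.0
        if gain > 1.0 and p.PERKT > 0 and g(p.PERKT) < 0:
            r = brentq(g, 1e-12, p.PERKT, xtol=1e-15)
            out.append((r, I_of(r)))
    else:
        if p.PERKT == 0:
            out.append((0.0, I_of(0.0)))
        elif g(1e-15) <= 0:
            out.append((0.0, I_of(0.0)))
        else:
            r = brentq(g, 1e-15, p.PERKT, xtol=1e-15)
            out.append((r, I_of(r)))
    return out


# -- inducer toggle ---------------------------------------------------------

def _auto_nullcline_roots(Y: float, uA: float, p: ParameterSet) -> list[float]:
    """Roots A of the autophagy nullcline (quadratic in A) within [0, AT]."""
    T, Jon, Joff = p.AT_auto, p.J_a_on, p.J_a_off
    d = p.k_da + p.k_x_aa * Y
    c2 = d - uA
    c1 = uA * (T - Joff) - d * (Jon + T)
    c0 = uA * T * Joff
    if abs(c2) < 1e-14:
        roots = [] if abs(c1) < 1e-14 else [-c0 / c1]
    else:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc < 0:
            return []
        sq = float(np.sqrt(disc))
        roots = [(-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)]
    return sorted(r for r in roots if -1e-12 <= r <= T + 1e-12)


def _apop_residual(A: float, Y: float, uY: float, p: ParameterSet) -> float:
    T, Jon, Joff = p.AT_apop, p.J_ap_on, p.J_ap_off
    d = p.k_dap + p.k_x_apa * A
    return uY * (T - Y) / (Jon + T - Y) - d * Y / (Joff + Y)


def _inducer_states(p: ParameterSet, P: float, I: float) -> list[tuple[float, float]]:
    uA = p.k_pa * P + p.k_ia * I
    uY = p.k_pap * P + p.k_iap * I
    T = p.AT_apop
    edge = np.geomspace(1e-7, 0.2 * max(T, 1e-6), 60)
    grid = np.unique(np.concatenate([edge, T - edge, np.linspace(0.0, T, 241)]))
    grid = grid[(grid >= 0.0) & (grid <= T)]

    found: list[tuple[float, float]] = []
    prev: dict[int, tuple[float, float, float]] = {}
    for Y in grid:
        cur: dict[int, tuple[float, float, float]] = {}
        for bi, A in enumerate(_auto_nullcline_roots(Y, uA, p)):
            cur[bi] = (Y, A, _apop_residual(A, Y, uY, p))
        for bi, (Y1, A1, h1) in cur.items():
            if bi not in prev:
                continue
            Y0, A0, h0 = prev[bi]
            if h0 == 0.0:
                found.append((A0, Y0))
            elif h0 * h1 < 0:
                def h(y, _bi=bi):
                    roots = _auto_nullcline_roots(y, uA, p)
                    if len(roots) <= _bi:
                        return np.nan
                    return _apop_residual(roots[_bi], y, uY, p)
                try:
                    yr = brentq(h, Y0, Y1, xtol=1e-14)
                    found.append((_auto_nullcline_roots(yr, uA, p)[bi], yr))
                except ValueError:
                    pass
        prev = cur

    dedup: list[tuple[float, float]] = []
    for a, y in found:
        if not any(abs(a - b) + abs(y - z) < 1e-8 for b, z in dedup):
            dedup.append((a, y))
    return dedup


def find_steady_states(p: ParameterSet, stress: float | None = None) -> list[SteadyState]:
    """All equilibria of the full system, stability-annotated.

    Stability is decided by the sign of the largest real part of the
    Jacobian's eigenvalues (stable iff below ``STABILITY_MARGIN``).
    """
    S = p.stress if stress is None else float(stress)
    q = p.with_stress(S)
    out: list[SteadyState] = []
    for (P, I) in _sensor_states(q, S):
        for (A, Y) in _inducer_states(q, P, I):
            y = np.array([P, I, A, Y])
            if np.max(np.abs(rhs(y, q))) > 1e-7:
                continue
            if any(np.max(np.abs(y - s.state)) < DEDUP_TOL for s in out):
                continue
            lam = float(np.max(np.linalg.eigvals(jacobian(y, q)).real))
            out.append(SteadyState(state=y, stable=lam < STABILITY_MARGIN, max_re_eig=lam))
    if not out:
        raise RuntimeError(
            "no equilibrium located: a continuous flow on the forward-invariant "
            "box must have at least one; this indicates a numerical failure")
    return out


def steady_states_by_relaxation(p: ParameterSet, stress: float | None = None,
                                grid_per_axis: int = 6, t_max: float = 400.0,
                                cluster_tol: float = 1e-4) -> list[np.ndarray]:
    """Brute-force oracle: integrate to convergence from a lattice of starts.

    Independent of the root-finding path; used to cross-check
    :func:`find_steady_states` (stable states only — relaxation cannot land on
    saddles).
    """
    S = p.stress if stress is None else float(stress)
    q = p.with_stress(S)
    axes = [np.linspace(0.02, 0.98, grid_per_axis) * t
            for t in (q.PERKT, q.IRE1T, q.AT_auto, q.AT_apop)]
    endpoints = []
    f = lambda t, y: rhs(y, q)
    for y0 in np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4):
        sol = solve_ivp(f, (0.0, t_max), y0, method="LSODA", rtol=1e-10, atol=1e-12)
        yf = sol.y[:, -1]
        if np.max(np.abs(rhs(yf, q))) < 1e-8:
            endpoints.append(yf)
    clusters: list[np.ndarray] = []
    for y in endpoints:
        for i, c in enumerate(clusters):
            if np.max(np.abs(y - c)) < cluster_tol:
                clusters[i] = 0.5 * (c + y)
                break
        else:
            clusters.append(y)
    return clusters


# -- signal-response curve --------------------------------------------------

def _has_branch(p: ParameterSet, S: float, which: str) -> bool:
    half = 0.5 * p.AT_apop
    for ss in find_steady_states(p, S):
        if ss.stable and ((ss.apop < half) == (which == "low")):
            return True
    return False


def _locate_fold(p: ParameterSet, which: str, grid: np.ndarray,
                 resolution: float) -> tuple[float | None, str]:
    """Edge of existence of a stable branch, refined by bisection.

    Returns (value, status) with status in {"found", "above_scan",
    "below_scan", "none"}.
    """
    present = [_has_branch(p, s, which) for s in grid]
    if which == "low":
        trans = [i for i in range(len(grid) - 1) if present[i] and not present[i + 1]]
        if not trans:
            return (None, "above_scan") if present[-1] else (None, "none")
        lo, hi = grid[trans[0]], grid[trans[0] + 1]
        while hi - lo > resolution:
            m = 0.5 * (lo + hi)
            if _has_branch(p, m, "low"):
                lo = m
            else:
                hi = m
        return 0.5 * (lo + hi), "found"
    trans = [i for i in range(len(grid) - 1) if not present[i] and present[i + 1]]
    if not trans:
        return (None, "below_scan") if present[0] else (None, "none")
    lo, hi = grid[trans[0]], grid[trans[0] + 1]
    while hi - lo > resolution:
        m = 0.5 * (lo + hi)
        if _has_branch(p, m, "high"):
            hi = m
        else:
            lo = m
    return 0.5 * (lo + hi), "found"


@dataclass
class SignalResponseCurve:
    """Stability-annotated steady-state branches of apoptosis versus stress.

    ``sn_on`` is the stress at which the low (survival) branch disappears —
    the activation threshold of the suicide switch; ``sn_off`` the stress at
    which the high (death) branch disappears — the deactivation threshold.
    Either may be flagged out of the scanned range.
    """
    stress: np.ndarray
    points: list[list[SteadyState]]
    sn_on: float | None
    sn_on_status: str
    sn_off: float | None
    sn_off_status: str
    params: ParameterSet
    branch_ids: list[list[int]] = field(default_factory=list)

    @property
    def bistable(self) -> bool:
        return self.max_coexisting_stable() >= 2

    def max_coexisting_stable(self) -> int:
        return max(sum(ss.stable for ss in col) for col in self.points)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, (s, col) in enumerate(zip(self.stress, self.points)):
            ids = self.branch_ids[j] if self.branch_ids else [-1] * len(col)
            for ss, bid in zip(col, ids):
                rows.append({
                    "stress": s, "perk": ss.state[0], "ire1": ss.state[1],
                    "auto": ss.state[2], "apop": ss.state[3],
                    "stability": "stable" if ss.stable else "unstable",
                    "branch_id": bid,
                })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "sn_on": self.sn_on, "sn_on_status": self.sn_on_status,
            "sn_off": self.sn_off, "sn_off_status": self.sn_off_status,
            "reversibility": classify_reversibility(self),
            "max_coexisting_stable_states": self.max_coexisting_stable(),
            "scan_min": float(self.stress[0]), "scan_max": float(self.stress[-1]),
            "n_points": int(len(self.stress)),
        }


def _assemble_branches(stress: np.ndarray, points: list[list[SteadyState]]) -> list[list[int]]:
    """Nearest-neighbour continuation across the stress grid.

    Ambiguities (two candidate continuations at comparable distance) are
    resolved by the smallest state-space jump.
    """
    next_id = 0
    ids: list[list[int]] = []
    prev: list[tuple[int, SteadyState]] = []
    for col in points:
        free = list(prev)
        col_ids: list[int] = []
        # order current states by best available match distance
        order = sorted(
            range(len(col)),
            key=lambda i: min((np.max(np.abs(col[i].state - s.state)) for _, s in free),
                              default=np.inf))
        assigned = {}
        for i in order:
            best, bdist = None, np.inf
            for k, (bid, s) in enumerate(free):
                d = float(np.max(np.abs(col[i].state - s.state)))
                if d < bdist:
                    best, bdist = k, d
            if best is not None and bdist < 0.2:
                bid, _ = free.pop(best)
                assigned[i] = bid
            else:
                assigned[i] = next_id
                next_id += 1
        col_ids = [assigned[i] for i in range(len(col))]
        ids.append(col_ids)
        prev = list(zip(col_ids, col))
    return ids


def signal_response(p: ParameterSet, stress_range: tuple[float, float] = (0.0, 60.0),
                    n_points: int = 600, fold_resolution: float = 0.01) -> SignalResponseCurve:
    """Scan steady states over a stress grid and locate the fold points."""
    lo, hi = stress_range
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(lo, hi, n_points)
    points = [find_steady_states(p, s) for s in grid]
    # fold refinement uses a decimated grid for bracketing (existence is
    # monotone between consecutive scan points at this resolution)
    coarse = grid[:: max(1, n_points // 120)]
    if coarse[-1] != grid[-1]:
        coarse = np.append(coarse, grid[-1])
    sn_on, on_status = _locate_fold(p, "low", coarse, fold_resolution)
    sn_off, off_status = _locate_fold(p, "high", coarse, fold_resolution)
    curve = SignalResponseCurve(
        stress=grid, points=points,
        sn_on=sn_on, sn_on_status=on_status,
        sn_off=sn_off, sn_off_status=off_status,
        params=p)
    curve.branch_ids = _assemble_branches(grid, points)
    return curve


def classify_reversibility(curve: SignalResponseCurve) -> str:
    """``irreversible`` | ``reversible`` | ``no_switch``.

    Irreversible: the death branch persists down to zero stress (its fold lies
    at or below the physical range), so washing the stressor out cannot undo
    commitment.  Reversible: the death branch disappears at positive stress.
    """
    if not curve.bistable:
        return "no_switch"
    if curve.sn_off_status == "below_scan":
        return "irreversible"
    if curve.sn_off_status == "found":
        return "irreversible" if curve.sn_off <= 0 else "reversible"
    return "no_switch"


def threshold_shift(curve_a: SignalResponseCurve, curve_b: SignalResponseCurve) -> float:
    """Signed shift SN_on(b) - SN_on(a), in stress units.

    A shifted threshold above the scanned range counts as +inf (the switch can
    no longer be engaged within physiological stress).
    """
    def val(c: SignalResponseCurve) -> float:
        if c.sn_on_status == "found":
            return c.sn_on
        if c.sn_on_status == "above_scan":
            return np.inf
        raise ValueError("curve has no activation fold (no stable low branch scanned)")
    a, b = val(curve_a), val(curve_b)
    if np.isinf(a) and np.isinf(b):
        return 0.0
    return b - a


def hysteresis_ramp(p: ParameterSet, s_max: float = 60.0, rate: float = 0.002,
                    threshold: float = 0.5) -> dict:
    """Slow up-then-down stress ramp in the time domain.

    Returns the stress values at which the apoptosis inducer jumps above /
    falls below ``threshold`` x total (or None), for comparison against the
    curve's folds.
    """
    q = p
    T = s_max / rate
    f = lambda t, y: rhs(y, q.with_stress(min(rate * t, s_max)))
    t_eval = np.linspace(0.0, T, 4001)
    up = solve_ivp(f, (0.0, T), np.zeros(4), method="LSODA",
                   rtol=1e-8, atol=1e-10, t_eval=t_eval, dense_output=False)
    apop = up.y[3]
    half = threshold * p.AT_apop
    i_up = np.argmax(apop > half) if np.any(apop > half) else None
    s_up = float(min(rate * up.t[i_up], s_max)) if i_up is not None else None

    g = lambda t, y: rhs(y, q.with_stress(max(s_max - rate * t, 0.0)))
    down = solve_ivp(g, (0.0, T), up.y[:, -1], method="LSODA",
                     rtol=1e-8, atol=1e-10, t_eval=t_eval)
    apop_d = down.y[3]
    i_dn = np.argmax(apop_d < half) if np.any(apop_d < half) else None
    s_down = float(max(s_max - rate * down.t[i_dn], 0.0)) if i_dn is not None else None
    return {"jump_up_stress": s_up, "jump_down_stress": s_down}
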