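"""Qualitative constraints on the network and constraint-based parameter search.

The experiments pin down qualitative behaviours rather than numbers, so the
default parameter set is required to satisfy a suite of machine-checkable
constraints: a bistable switch whose activation threshold separates the two
printed stress levels, irreversibility of the intact network, the two
knockdown threshold shifts with loss of irreversibility, mutual exclusion of
the two inducers, survival-before-death ordering, and a decaying transient
apoptosis excursion at survivable stress.  Parameter search is seeded
log-uniform sampling scored against the same constraints (reproducibility
and coverage reporting are preferred over optimiser speed at this model
size).
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .bifurcation import SignalResponseCurve, signal_response
from .params import DEFAULT_PARAMS, ParameterSet, preset
from .phenotype import ONSET_FRACTION, TRANSIENT_FRACTION, extract_features
from .protocols import run_scenario

__all__ = [
    "ConstraintReport",
    "CONSTRAINT_NAMES",
    "check_constraints",
    "search_parameters",
    "robustness_table",
    "SEARCH_BOUNDS",
]

CONSTRAINT_NAMES = (
    "bistable_window",            # two stable + one unstable state coexist
    "irreversible_default",       # death branch persists to zero stress
    "thresholds_bracket_scenarios",  # 25 < SN_on < 40
    "transient_apoptosis_low_stress",  # stress 25: excursion that recedes
    "siperk_rightshift_reversible",    # PERKT*0.2: SN_on > 40, SN_off > 0
    "ire1_leftshift_reversible",       # IRE1T*0.1: SN_on < default, SN_off > 0
    "mutual_exclusion",           # inducers never both high at steady state
    "autophagy_before_apoptosis",  # survival window precedes death at 40
)


@dataclass
class ConstraintReport:
    results: dict[str, bool]
    measured: dict[str, object]

    @property
    def feasible(self) -> bool:
        return all(self.results.values())

    def to_dict(self) -> dict:
        return {"feasible": self.feasible, "results": dict(self.results),
                "measured": {k: v for k, v in self.measured.items()}}


def _sn_on_value(curve: SignalResponseCurve) -> float:
    if curve.sn_on_status == "found":
        return float(curve.sn_on)
    return np.inf if curve.sn_on_status == "above_scan" else np.nan


def check_constraints(params: ParameterSet = DEFAULT_PARAMS,
                      stress_range: tuple[float, float] = (0.0, 60.0),
                      n_points: int = 121,
                      skip_dynamics: bool = False) -> ConstraintReport:
    """Evaluate the full qualitative constraint suite on one parameter set.

    ``n_points`` controls the scan density of the three signal-response
    curves (folds are bisection-refined regardless).  A constraint whose
    evaluation fails numerically is marked failed with the error recorded.
    """
    results: dict[str, bool] = {}
    measured: dict[str, object] = {}
    try:
        curve = signal_response(params, stress_range, n_points)
        sp = preset("siPERK", params)
        il = preset("IRE1-inhibited", params)
        curve_sp = signal_response(sp, stress_range, n_points)
        curve_il = signal_response(il, stress_range, n_points)
    except Exception as exc:  # pragma: no cover - numerical failure path
        for name in CONSTRAINT_NAMES:
            results[name] = False
        measured["error"] = f"scan failed: {exc}"
        return ConstraintReport(results, measured)

    nmax = curve.max_coexisting_stable()
    results["bistable_window"] = nmax == 2
    measured["max_coexisting_stable_states"] = nmax

    rev = curve.sn_off_status == "below_scan" or (
        curve.sn_off_status == "found" and curve.sn_off <= 0)
    results["irreversible_default"] = rev
    measured["sn_off_default"] = (curve.sn_off if curve.sn_off_status == "found"
                                  else curve.sn_off_status)

    on_d = _sn_on_value(curve)
    results["thresholds_bracket_scenarios"] = bool(25.0 < on_d < 40.0)
    measured["sn_on_default"] = on_d

    on_sp = _sn_on_value(curve_sp)
    off_sp = curve_sp.sn_off if curve_sp.sn_off_status == "found" else np.nan
    results["siperk_rightshift_reversible"] = bool(on_sp > 40.0 and off_sp > 0)
    measured["sn_on_siperk"] = on_sp
    measured["sn_off_siperk"] = off_sp

    on_il = _sn_on_value(curve_il)
    off_il = curve_il.sn_off if curve_il.sn_off_status == "found" else np.nan
    results["ire1_leftshift_reversible"] = bool(on_il < on_d and off_il > 0)
    measured["sn_on_ire1"] = on_il
    measured["sn_off_ire1"] = off_il

    # mutual exclusion across every scanned stable state of all three curves
    excl = True
    for c, pp in ((curve, params), (curve_sp, sp), (curve_il, il)):
        for col in c.points:
            for ss in col:
                if (ss.stable and ss.state[2] > 0.5 * pp.AT_auto
                        and ss.state[3] > 0.5 * pp.AT_apop):
                    excl = False
    results["mutual_exclusion"] = excl

    if skip_dynamics:
        results["transient_apoptosis_low_stress"] = False
        results["autophagy_before_apoptosis"] = False
        measured["dynamics"] = "skipped"
        return ConstraintReport(results, measured)

    try:
        low = run_scenario("low_stress", params)
        apop = low.series("apop")
        theta = TRANSIENT_FRACTION * params.AT_apop
        ok4 = bool(apop.max() >= theta and apop[-1] < theta
                   and apop[-1] < 0.5 * params.AT_apop)
        results["transient_apoptosis_low_stress"] = ok4
        measured["low_stress_apop_peak"] = float(apop.max())
        measured["low_stress_apop_final"] = float(apop[-1])

        high = run_scenario("high_stress", params)
        auto, apop_h = high.series("auto"), high.series("apop")
        t_auto_peak = float(high.time[int(np.argmax(auto))])
        f = extract_features(high.time, apop_h, scale=params.AT_apop)
        onset = f.onset
        ok8 = bool(onset is not None and t_auto_peak < onset
                   and apop_h[-1] > 0.5 * params.AT_apop
                   and auto[-1] < 0.5 * params.AT_auto)
        results["autophagy_before_apoptosis"] = ok8
        measured["autophagy_peak_time"] = t_auto_peak
        measured["apoptosis_onset_time"] = onset
        # steady-state exclusion along trajectories' final points
        if apop_h[-1] > 0.5 * params.AT_apop and auto[-1] > 0.5 * params.AT_auto:
            results["mutual_exclusion"] = False
    except Exception as exc:  # pragma: no cover
        results["transient_apoptosis_low_stress"] = False
        results["autophagy_before_apoptosis"] = False
        measured["dynamics_error"] = str(exc)

    return ConstraintReport(results, measured)


#: shipped search bounds: +-25 % boxes around the calibrated default for the
#: inducer-layer parameters (the sensor layer sets the time base and the
#: stress scale and is held fixed during search)
_SEARCH_KEYS = ("k_pa", "k_ia", "k_pap", "k_iap", "k_da", "k_dap",
                "k_x_aa", "k_x_apa", "J_a_on", "J_a_off", "J_ap_on", "J_ap_off")
SEARCH_BOUNDS = {k: (0.8 * getattr(DEFAULT_PARAMS, k), 1.25 * getattr(DEFAULT_PARAMS, k))
                 for k in _SEARCH_KEYS}


def search_parameters(bounds: dict | None = None, n_samples: int = 100, seed: int = 0,
                      base: ParameterSet = DEFAULT_PARAMS,
                      n_points: int = 61) -> tuple[list[ParameterSet], pd.DataFrame]:
    """Log-uniform random search scored by the constraint suite.

    Returns the feasible sets and a per-constraint pass-rate table over the
    sample.  Candidates violating the wiring invariants (strong/weak arrow
    ordering) are discarded before scoring.
    """
    bounds = dict(SEARCH_BOUNDS if bounds is None else bounds)
    rng = np.random.default_rng(seed)
    counts = {name: 0 for name in CONSTRAINT_NAMES}
    n_scored = 0
    feasible: list[ParameterSet] = []
    for _ in range(n_samples):
        draw = {k: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                for k, (lo, hi) in bounds.items()}
        cand = base.replace(**draw)
        try:
            cand.validate_wiring()
        except ValueError:
            continue
        rep = check_constraints(cand, n_points=n_points)
        n_scored += 1
        for name, ok in rep.results.items():
            counts[name] += bool(ok)
        if rep.feasible:
            feasible.append(cand)
    rates = pd.DataFrame({
        "constraint": list(counts),
        "pass_rate": [counts[k] / n_scored if n_scored else np.nan for k in counts],
    })
    if not feasible and n_scored:
        worst = rates.sort_values("pass_rate").iloc[0]
        rates.attrs["diagnostic"] = (f"no feasible set in {n_scored} scored samples; "
                                     f"most violated: {worst['constraint']}")
    return feasible, rates


def robustness_table(params: ParameterSet = DEFAULT_PARAMS, rel: float = 0.1,
                     keys: tuple[str, ...] | None = None,
                     n_points: int = 61) -> pd.DataFrame:
    """Single-parameter +-``rel`` perturbations re-scored against all constraints.

    Failures are reported, not hidden: the model claims qualitative, not
    fine-tuned, behaviour, and this table quantifies how far that holds.
    """
    if keys is None:
        keys = tuple(k for k in (f.name for f in fields(ParameterSet))
                     if k.startswith(("k_", "J_")))
    rows = []
    for k in keys:
        for sign in (+1, -1):
            val = getattr(params, k) * (1 + sign * rel)
            rep = check_constraints(params.replace(**{k: val}), n_points=n_points)
            rows.append({"parameter": k, "factor": 1 + sign * rel,
                         "feasible": rep.feasible,
                         **{f"pass_{n}": rep.results[n] for n in CONSTRAINT_NAMES}})
    return pd.DataFrame(rows)
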