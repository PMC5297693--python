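"""Synthetic densitometry-style marker time courses and recovery studies.

The generator emulates the statistical structure of immunoblot band-density
panels: marker time courses sampled at fixed intervals, normalised to the
series maximum (relative band density), with multiplicative lognormal noise
of a chosen coefficient of variation, in replicate sets (default three, the
usual "three parallel experiments" design).  One model time unit is labelled
as 30 minutes so the high-stress death switch falls in the 90-120 min range
of the experimental panels; the mapping is cosmetic and has no dynamical
consequence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DEFAULT_PARAMS, ParameterSet
from .phenotype import MARKER_MAP, PhenotypeCall, call_phenotype, extract_features
from .protocols import Trajectory, run_scenario

__all__ = [
    "SyntheticTimecourse",
    "generate_timecourse",
    "classify_timecourse",
    "recovery_study",
    "MINUTES_PER_TIME_UNIT",
]

MINUTES_PER_TIME_UNIT = 30.0


@dataclass
class SyntheticTimecourse:
    """One replicate of normalised marker intensities on a sampling grid."""
    time: np.ndarray                 # model time units
    intensities: dict[str, np.ndarray]   # marker -> values, >= 0, ~[0, 1+noise]
    replicate: int
    cv: float
    seed: int
    scenario: str
    params: ParameterSet

    @property
    def minutes(self) -> np.ndarray:
        return self.time * MINUTES_PER_TIME_UNIT

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for marker, vals in self.intensities.items():
            rows.append(pd.DataFrame({
                "time": self.time, "marker": marker, "replicate": self.replicate,
                "intensity": vals,
            }))
        return pd.concat(rows, ignore_index=True)


def _normalised_marker_curves(traj: Trajectory, sampling_interval: float):
    if sampling_interval > traj.time[-1]:
        raise ValueError("sampling interval exceeds the trajectory horizon")
    t = np.arange(0.0, traj.time[-1] + 1e-9, sampling_interval)
    curves = {}
    for var, markers in MARKER_MAP.items():
        v = np.interp(t, traj.time, traj.series(var))
        peak = v.max()
        norm = v / peak if peak > 0 else v
        for m in markers:
            curves[m] = norm
    return t, curves


def generate_timecourse(params: ParameterSet = DEFAULT_PARAMS, scenario: str = "high_stress",
                        sampling_interval: float = 0.5, n_replicates: int = 3,
                        cv: float = 0.1, seed: int = 0) -> list[SyntheticTimecourse]:
    """Simulate a scenario and emit noisy normalised marker replicates.

    Each marker series is the scenario trajectory of its model variable,
    sampled every ``sampling_interval`` time units, normalised to its own
    maximum, then multiplied by unit-mean lognormal noise with coefficient of
    variation ``cv``.  Replicates use independent sub-seeds spawned from
    ``seed``; the output is fully deterministic in (seed, inputs).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    traj = run_scenario(scenario, params)
    t, curves = _normalised_marker_curves(traj, sampling_interval)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    out = []
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        noisy = {}
        for m, base in curves.items():
            if cv == 0:
                noisy[m] = base.copy()
            else:
                factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                                        size=base.shape)
                noisy[m] = base * factors
        out.append(SyntheticTimecourse(time=t, intensities=noisy, replicate=r,
                                       cv=cv, seed=seed, scenario=scenario,
                                       params=params))
    return out


def classify_timecourse(tc: SyntheticTimecourse,
                        reference_onset: float | None) -> PhenotypeCall:
    """Phenotype call from one replicate's normalised marker panel.

    Markers belonging to the same model variable are averaged before feature
    extraction (as a densitometrist would read concordant bands together).
    """
    def pooled(var: str) -> np.ndarray:
        return np.mean([tc.intensities[m] for m in MARKER_MAP[var]], axis=0)

    apop = extract_features(tc.time, pooled("apop"))
    auto = extract_features(tc.time, pooled("auto"))
    return call_phenotype(apop, reference_onset, auto=auto)


def _reference_onset(params: ParameterSet, sampling_interval: float) -> float | None:
    ref = generate_timecourse(params, "high_stress", sampling_interval,
                              n_replicates=1, cv=0.0, seed=0)[0]
    return classify_timecourse(ref, None).apop_onset


def recovery_study(params: ParameterSet = DEFAULT_PARAMS,
                   scenarios: tuple[str, ...] = ("low_stress", "high_stress",
                                                 "siPERK_high_stress",
                                                 "IRE1low_high_stress"),
                   cv_grid: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2),
                   n_replicates: int = 200, seed: int = 0,
                   sampling_interval: float = 0.5) -> pd.DataFrame:
    """Fraction of noisy replicates whose phenotype matches the noiseless call.

    Returns a tidy frame (scenario, cv, recovery, noiseless_phenotype).
    """
    ref_onset = _reference_onset(params, sampling_interval)
    rows = []
    for scen in scenarios:
        clean = generate_timecourse(params, scen, sampling_interval, 1, 0.0, seed)[0]
        truth = classify_timecourse(clean, ref_onset).phenotype
        for cv in cv_grid:
            reps = generate_timecourse(params, scen, sampling_interval,
                                       n_replicates, cv, seed)
            calls = [classify_timecourse(r, ref_onset).phenotype for r in reps]
            rows.append({"scenario": scen, "cv": cv,
                         "recovery": float(np.mean([c == truth for c in calls])),
                         "noiseless_phenotype": truth})
    return pd.DataFrame(rows)
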