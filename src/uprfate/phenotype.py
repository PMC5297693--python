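"""Timing features and phenotype calls (survival / death / delayed death).

Feature extraction works on any near-uniformly sampled series.  Thresholds
are fractions of a scale: the variable's conserved total for model
trajectories, or the series maximum for densitometry-style normalised marker
readouts.  A "sustained" crossing must hold for K consecutive samples, which
rejects single-sample noise spikes at the synthetic generator's default
sampling density.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocols import Trajectory

__all__ = [
    "Features",
    "PhenotypeCall",
    "extract_features",
    "call_phenotype",
    "phenotype_of_trajectory",
    "MARKER_MAP",
    "VARIABLE_OF_MARKER",
]

#: model variable -> experimental marker proxies (immunoblot / RT-PCR panels)
MARKER_MAP = {
    "auto": ("LC3-II", "ULK-555-P"),
    "apop": ("cleaved PARP", "CHOP", "JNK-P"),
    "perk": ("eiF2a-P",),
    "ire1": ("XBP1s",),
}
VARIABLE_OF_MARKER = {m: v for v, ms in MARKER_MAP.items() for m in ms}

#: sustained-crossing threshold (fraction of scale), run length, and the
#: lower transient-excursion threshold
ONSET_FRACTION = 0.5
SUSTAIN_SAMPLES = 3
TRANSIENT_FRACTION = 0.05


@dataclass(frozen=True)
class Features:
    window: float               # total time spent above the onset threshold
    onset: float | None         # first sustained crossing, or None
    transient: bool             # crossed the transient threshold, then receded
    peak: float
    final: float
    scale: float
    dt: float


@dataclass(frozen=True)
class PhenotypeCall:
    phenotype: str              # survival | death | delayed_death | undetermined
    apop_onset: float | None
    autophagy_window: float
    transient_apoptosis: bool

    def __post_init__(self):
        if self.phenotype == "death" and self.apop_onset is None:
            raise ValueError("death call requires an apoptosis onset")
        if self.phenotype == "survival" and self.apop_onset is not None and not self.transient_apoptosis:
            raise ValueError("survival with an onset requires the transient flag")


def extract_features(time, values, scale: float | None = None,
                     onset_fraction: float = ONSET_FRACTION,
                     transient_fraction: float = TRANSIENT_FRACTION,
                     sustain: int = SUSTAIN_SAMPLES) -> Features:
    """Window above threshold, sustained-onset time and transient flag.

    ``scale`` defaults to the series maximum (densitometry-style); pass the
    variable's total for absolute trajectories.  Raises on series shorter
    than the sustain run length.
    """
    t = np.asarray(time, float)
    v = np.asarray(values, float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("time and values must be 1-D and equally long")
    if len(v) < sustain:
        raise ValueError(f"series shorter than {sustain} samples is undetermined")
    base = float(np.max(v)) if scale is None else float(scale)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if base <= 0:
        return Features(0.0, None, False, float(np.max(v)), float(v[-1]), base, dt)

    theta = onset_fraction * base
    above = v >= theta
    window = float(np.sum(above) * dt)
    onset = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain:
            onset = float(t[i - sustain + 1])
            break
    theta_t = transient_fraction * base
    transient = bool(np.max(v) >= theta_t and v[-1] < theta_t)
    return Features(window=window, onset=onset, transient=transient,
                    peak=float(np.max(v)), final=float(v[-1]), scale=base, dt=dt)


def call_phenotype(apop: Features, reference_onset: float | None,
                   auto: Features | None = None) -> PhenotypeCall:
    """Classify a trajectory/readout against the reference death onset.

    Death: sustained apoptosis onset; delayed death: onset later than the
    reference by more than one sampling step; survival otherwise.  When
    autophagy features are supplied (max-normalised marker mode, where an
    apoptosis plateau at a few percent of total still normalises to 1) a
    high autophagy end state overrides: sustained autophagy at the end of
    the horizon is the survival signature.
    """
    survival_by_autophagy = (auto is not None
                             and auto.final >= ONSET_FRACTION * auto.scale)
    onset = apop.onset
    if survival_by_autophagy or onset is None:
        return PhenotypeCall(
            phenotype="survival",
            apop_onset=None,
            autophagy_window=auto.window if auto is not None else 0.0,
            transient_apoptosis=apop.transient)
    delayed = reference_onset is not None and onset > reference_onset + apop.dt
    return PhenotypeCall(
        phenotype="delayed_death" if delayed else "death",
        apop_onset=onset,
        autophagy_window=auto.window if auto is not None else 0.0,
        transient_apoptosis=apop.transient)


def phenotype_of_trajectory(traj: Trajectory, reference_onset: float | None = None,
                            onset_fraction: float = ONSET_FRACTION) -> PhenotypeCall:
    """Phenotype call on a model trajectory (absolute scale, totals known)."""
    p = traj.params
    apop = extract_features(traj.time, traj.series("apop"), scale=p.AT_apop,
                            onset_fraction=onset_fraction)
    auto = extract_features(traj.time, traj.series("auto"), scale=p.AT_auto,
                            onset_fraction=onset_fraction)
    # absolute mode: the spec rule — death iff sustained apoptosis onset
    if apop.onset is None:
        return PhenotypeCall(phenotype="survival", apop_onset=None,
                             autophagy_window=auto.window,
                             transient_apoptosis=apop.transient)
    delayed = reference_onset is not None and apop.onset > reference_onset + apop.dt
    return PhenotypeCall(phenotype="delayed_death" if delayed else "death",
                         apop_onset=apop.onset,
                         autophagy_window=auto.window,
                         transient_apoptosis=apop.transient)
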