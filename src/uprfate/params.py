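"""Model parameters, named presets and structured-text configuration.

The model tracks four activities: the ER-stress sensors PERK and IRE-1 and the
lumped autophagy ("survival") and apoptosis ("suicide") inducers.  All totals
are in arbitrary units with default 1.0; the stress signal is dimensionless
(the printed scenario values are 25 = survivable and 40 = lethal).  Time is
dimensionless throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import yaml

__all__ = [
    "ParameterSet",
    "DEFAULT_PARAMS",
    "PRESETS",
    "apply_perturbation",
    "preset",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants, coupling weights, totals and the stress signal.

    The defaults are the package's calibrated reference set: they place the
    apoptosis activation threshold between the two printed stress levels,
    make the intact switch irreversible, and reproduce the knockdown
    threshold shifts (see docs/methods.md).
    """

    # input signal
    stress: float = 0.0
    # totals (conserved: active + inactive = total)
    PERKT: float = 1.0
    IRE1T: float = 1.0
    AT_auto: float = 1.0
    AT_apop: float = 1.0
    # sensor layer: stress activation, mutual (positive-feedback) activation,
    # first-order inactivation
    k_sp: float = 0.05
    k_si: float = 0.05
    k_ip: float = 5.0
    k_pi: float = 5.0
    k_dp: float = 3.0
    k_di: float = 3.0
    # autophagy inducer: weighted sensor activation (IRE-1 arm dominant),
    # saturating activation/inactivation fluxes
    k_pa: float = 2.563
    k_ia: float = 11.65
    k_da: float = 0.1559
    k_x_aa: float = 17.47       # apoptosis -> autophagy inhibition
    J_a_on: float = 1.041
    J_a_off: float = 0.0705
    # apoptosis inducer: weighted sensor activation (PERK arm dominant),
    # zero-order (sharp) activation/inactivation fluxes
    k_pap: float = 1.5
    k_iap: float = 0.3
    k_dap: float = 0.3223
    k_x_apa: float = 1.285      # autophagy -> apoptosis inhibition
    J_ap_on: float = 0.0108
    J_ap_off: float = 0.0174

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")

    def validate_wiring(self) -> None:
        """Check the qualitative wiring of the reference network.

        Strong/weak arrow ordering (IRE-1 dominant on autophagy, PERK dominant
        on apoptosis), presence of the sensor positive feedback and of the
        inducer double-negative loop.
        """
        if not self.k_ia > self.k_pa:
            raise ValueError("wiring requires k_ia > k_pa (IRE-1 strong on autophagy)")
        if not self.k_pap > self.k_iap:
            raise ValueError("wiring requires k_pap > k_iap (PERK strong on apoptosis)")
        if not (self.k_ip > 0 and self.k_pi > 0):
            raise ValueError("wiring requires the PERK<->IRE-1 positive feedback")
        if not (self.k_x_aa > 0 and self.k_x_apa > 0):
            raise ValueError("wiring requires the autophagy<->apoptosis double-negative loop")

    # -- convenience -------------------------------------------------------
    def with_stress(self, stress: float) -> "ParameterSet":
        return replace(self, stress=float(stress))

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


DEFAULT_PARAMS = ParameterSet()


def apply_perturbation(params: ParameterSet, target: str, fraction: float) -> ParameterSet:
    """Scale one sensor total, mimicking an siRNA knockdown / inhibition.

    ``target`` is ``"PERK"`` or ``"IRE1"``; ``fraction`` lies in (0, 1] and
    multiplies the corresponding total.  All other parameters are untouched.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if target == "PERK":
        return replace(params, PERKT=params.PERKT * fraction)
    if target == "IRE1":
        return replace(params, IRE1T=params.IRE1T * fraction)
    raise ValueError(f"unknown perturbation target {target!r} (expected 'PERK' or 'IRE1')")


#: Named perturbation presets.  The siPERK level follows the simulation
#: caption (total reduced to 0.2); IRE-1 inhibition reduces the total to 0.1.
PRESETS = {
    "default": lambda p: p,
    "siPERK": lambda p: apply_perturbation(p, "PERK", 0.2),
    "IRE1-inhibited": lambda p: apply_perturbation(p, "IRE1", 0.1),
}


def preset(name: str, params: ParameterSet | None = None) -> ParameterSet:
    """Return a preset-perturbed copy of ``params`` (default: shipped set)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](params if params is not None else DEFAULT_PARAMS)


# -- flat structured-text configuration ------------------------------------

def save_config(params: ParameterSet, path, scenarios: dict | None = None) -> None:
    """Write a flat ``parameters:`` mapping plus optional named scenarios."""
    doc = {"parameters": params.as_dict()}
    if scenarios:
        doc["scenarios"] = scenarios
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[ParameterSet, dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'parameters' section")
    return ParameterSet.from_dict(doc["parameters"]), doc.get("scenarios", {})
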