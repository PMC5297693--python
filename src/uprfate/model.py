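"""Right-hand side and Jacobian of the four-variable stress-response ODE.

State ordering is ``(perk, ire1, auto, apop)``: active PERK, active IRE-1,
active autophagy inducer, active apoptosis inducer.  Each variable lives in
the box [0, total]; activation draws on the inactive pool so the box is
forward-invariant.

Sensors follow mass-action activation of the inactive pool with first-order
inactivation,

    d perk/dt = (k_sp*stress + k_ip*ire1) * (PERKT - perk) - k_dp*perk

(and symmetrically for IRE-1, closing the positive feedback loop).  Inducers
follow Goldbeter-Koshland-type saturating activation/inactivation in which
the opposing inducer raises the inactivation rate — the double-negative
(toggle) loop:

    d auto/dt = uA*(AT-auto)/(J_on+AT-auto) - (k_da+k_x_aa*apop)*auto/(J_off+auto)

with activating input ``uA = k_pa*perk + k_ia*ire1`` and analogously for the
apoptosis inducer with input ``k_pap*perk + k_iap*ire1``.
"""
from __future__ import annotations

import numpy as np

from .params import ParameterSet

__all__ = ["rhs", "jacobian", "STATE_NAMES", "clip_to_box", "box_totals"]

STATE_NAMES = ("perk", "ire1", "auto", "apop")


def box_totals(p: ParameterSet) -> np.ndarray:
    return np.array([p.PERKT, p.IRE1T, p.AT_auto, p.AT_apop])


def clip_to_box(y, p: ParameterSet) -> np.ndarray:
    return np.clip(np.asarray(y, float), 0.0, box_totals(p))


def _check_state(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (4,):
        raise ValueError(f"state must have 4 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state: {y}")
    return y


def rhs(y, p: ParameterSet) -> np.ndarray:
    """Instantaneous rates (a.u. per time unit) at state ``y``."""
    P, I, A, Y = _check_state(y)
    dP = (p.k_sp * p.stress + p.k_ip * I) * (p.PERKT - P) - p.k_dp * P
    dI = (p.k_si * p.stress + p.k_pi * P) * (p.IRE1T - I) - p.k_di * I
    uA = p.k_pa * P + p.k_ia * I
    uY = p.k_pap * P + p.k_iap * I
    dA = (uA * (p.AT_auto - A) / (p.J_a_on + p.AT_auto - A)
          - (p.k_da + p.k_x_aa * Y) * A / (p.J_a_off + A))
    dY = (uY * (p.AT_apop - Y) / (p.J_ap_on + p.AT_apop - Y)
          - (p.k_dap + p.k_x_apa * A) * Y / (p.J_ap_off + Y))
    return np.array([dP, dI, dA, dY])


def jacobian(y, p: ParameterSet) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` at state ``y``."""
    P, I, A, Y = _check_state(y)
    J = np.zeros((4, 4))
    # sensors
    J[0, 0] = -(p.k_sp * p.stress + p.k_ip * I) - p.k_dp
    J[0, 1] = p.k_ip * (p.PERKT - P)
    J[1, 0] = p.k_pi * (p.IRE1T - I)
    J[1, 1] = -(p.k_si * p.stress + p.k_pi * P) - p.k_di

    # autophagy inducer
    uA = p.k_pa * P + p.k_ia * I
    fA = (p.AT_auto - A) / (p.J_a_on + p.AT_auto - A)
    dfA = -p.J_a_on / (p.J_a_on + p.AT_auto - A) ** 2
    gA = A / (p.J_a_off + A)
    dgA = p.J_a_off / (p.J_a_off + A) ** 2
    inactA = p.k_da + p.k_x_aa * Y
    J[2, 0] = p.k_pa * fA
    J[2, 1] = p.k_ia * fA
    J[2, 2] = uA * dfA - inactA * dgA
    J[2, 3] = -p.k_x_aa * gA

    # apoptosis inducer
    uY = p.k_pap * P + p.k_iap * I
    fY = (p.AT_apop - Y) / (p.J_ap_on + p.AT_apop - Y)
    dfY = -p.J_ap_on / (p.J_ap_on + p.AT_apop - Y) ** 2
    gY = Y / (p.J_ap_off + Y)
    dgY = p.J_ap_off / (p.J_ap_off + Y) ** 2
    inactY = p.k_dap + p.k_x_apa * A
    J[3, 0] = p.k_pap * fY
    J[3, 1] = p.k_iap * fY
    J[3, 3] = uY * dfY - inactY * dgY
    J[3, 2] = -p.k_x_apa * gY
    return J
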