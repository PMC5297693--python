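"""Export / parse of the model in the XPP ``.ode`` dialect.

The exporter writes one ``dX/dt=...`` line per variable, ``param`` lines,
``init`` lines and the ``done`` terminator, matching the dialect accepted by
XPPAUT.  The companion parser reads files written by this exporter (its own
dialect) back into a :class:`~uprfate.params.ParameterSet`, making the pair a
lossless round trip.
"""
from __future__ import annotations

import re
from dataclasses import fields

from .params import ParameterSet

__all__ = ["export_ode", "parse_ode"]

_EQUATIONS = """\
dperk/dt=(k_sp*stress+k_ip*ire1)*(PERKT-perk)-k_dp*perk
dire1/dt=(k_si*stress+k_pi*perk)*(IRE1T-ire1)-k_di*ire1
dauto/dt=(k_pa*perk+k_ia*ire1)*(AT_auto-auto)/(J_a_on+AT_auto-auto)-(k_da+k_x_aa*apop)*auto/(J_a_off+auto)
dapop/dt=(k_pap*perk+k_iap*ire1)*(AT_apop-apop)/(J_ap_on+AT_apop-apop)-(k_dap+k_x_apa*auto)*apop/(J_ap_off+apop)
"""


def export_ode(params: ParameterSet, init=(0.0, 0.0, 0.0, 0.0)) -> str:
    """Render the model and a parameter set as XPP ``.ode`` text."""
    lines = ["# ER-stress life-and-death decision network (UPR sensor/toggle model)"]
    lines += _EQUATIONS.rstrip("\n").split("\n")
    for f in fields(ParameterSet):
        lines.append(f"param {f.name}={getattr(params, f.name):.17g}")
    for name, v in zip(("perk", "ire1", "auto", "apop"), init):
        lines.append(f"init {name}={v:.17g}")
    lines.append("done")
    return "\n".join(lines) + "\n"


_PARAM_RE = re.compile(r"^\s*param\s+(\w+)\s*=\s*([-+0-9.eE]+)\s*$")
_INIT_RE = re.compile(r"^\s*init\s+(\w+)\s*=\s*([-+0-9.eE]+)\s*$")


def parse_ode(text: str) -> tuple[ParameterSet, dict[str, float]]:
    """Parse exporter-dialect ``.ode`` text into (parameters, initial values)."""
    values: dict[str, float] = {}
    init: dict[str, float] = {}
    n_deriv = 0
    saw_done = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "done":
            saw_done = True
            break
        if re.match(r"^d\w+/dt\s*=", line):
            n_deriv += 1
            continue
        m = _PARAM_RE.match(line)
        if m:
            values[m.group(1)] = float(m.group(2))
            continue
        m = _INIT_RE.match(line)
        if m:
            init[m.group(1)] = float(m.group(2))
            continue
        raise ValueError(f"unrecognised .ode line: {raw!r}")
    if not saw_done:
        raise ValueError("missing 'done' terminator")
    if n_deriv != 4:
        raise ValueError(f"expected 4 derivative lines, found {n_deriv}")
    return ParameterSet.from_dict(values), init
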