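"""Stress protocols and trajectory integration.

A protocol is a piecewise-constant stress schedule applied to an initial
state (default: everything inactive).  Integration is stiff-capable (LSODA)
with tight tolerances and restarts at every schedule discontinuity, so no
interpolation happens across a stress step.

The registered scenarios mirror the simulated experiments: sustained low
(stress = 25) or high (stress = 40) ER stress from the resting state, the two
sensor knockdowns under high stress, and a stressor wash-out applied after
commitment to apoptosis.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import box_totals, rhs
from .params import DEFAULT_PARAMS, ParameterSet, preset

__all__ = [
    "Protocol",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "run_scenario",
    "commitment_time",
    "SCENARIOS",
    "DEFAULT_HORIZON",
    "DEFAULT_DT",
]

#: default horizon (time units): all registered scenarios settle well within it
DEFAULT_HORIZON = 60.0
#: default output sampling step
DEFAULT_DT = 0.25
#: |rhs| below this at the final time marks the trajectory as settled
SETTLE_TOL = 1e-6

RTOL, ATOL = 1e-8, 1e-10


class IntegrationError(RuntimeError):
    def __init__(self, msg: str, last_valid_time: float):
        super().__init__(f"{msg} (last valid time {last_valid_time:g})")
        self.last_valid_time = last_valid_time


@dataclass(frozen=True)
class Protocol:
    """Initial state, stress schedule, optional perturbation preset, horizon.

    ``schedule`` is a sequence of (start_time, stress) segments with strictly
    increasing start times, the first at t = 0.
    """
    schedule: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    preset: str | None = None
    horizon: float = DEFAULT_HORIZON
    dt: float = DEFAULT_DT
    initial_state: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.dt <= 0:
            raise ValueError("sampling step must be > 0")
        times = [t for t, _ in self.schedule]
        if not times or times[0] != 0.0:
            raise ValueError("schedule must start at t = 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if any(s < 0 for _, s in self.schedule):
            raise ValueError("stress values must be >= 0")

    def stress_at(self, t: float) -> float:
        s = self.schedule[0][1]
        for t0, v in self.schedule:
            if t >= t0:
                s = v
        return s


@dataclass
class Trajectory:
    """Time-indexed model states under a protocol, with event markers."""
    time: np.ndarray
    states: np.ndarray          # shape (n_times, 4)
    stress: np.ndarray          # applied stress at each time
    events: tuple[float, ...]   # times of stress changes
    protocol: Protocol
    params: ParameterSet
    settled: bool = False

    def series(self, name: str) -> np.ndarray:
        idx = {"perk": 0, "ire1": 1, "auto": 2, "apop": 3}[name]
        return self.states[:, idx]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame (time, variable, value, scenario)."""
        rows = []
        for j, name in enumerate(("perk", "ire1", "auto", "apop")):
            rows.append(pd.DataFrame({
                "time": self.time, "variable": name,
                "value": self.states[:, j],
                "scenario": self.protocol.name or "custom",
            }))
        return pd.concat(rows, ignore_index=True)


def integrate(params: ParameterSet, protocol: Protocol) -> Trajectory:
    """Integrate the model under a protocol, segment by segment."""
    p = preset(protocol.preset, params) if protocol.preset else params
    n = int(round(protocol.horizon / protocol.dt)) + 1
    t_grid = np.linspace(0.0, protocol.horizon, n)

    seg_starts = [t for t, _ in protocol.schedule if t < protocol.horizon]
    seg_bounds = seg_starts + [protocol.horizon]
    y = np.asarray(protocol.initial_state, float)
    totals = box_totals(p)
    if np.any(y < -1e-12) or np.any(y > totals + 1e-12):
        raise ValueError("initial state outside the [0, total] box")

    times, states = [np.array([0.0])], [y[None, :]]
    for a, b in zip(seg_bounds, seg_bounds[1:]):
        q = p.with_stress(protocol.stress_at(a))
        t_eval = t_grid[(t_grid > a) & (t_grid <= b)]
        f = lambda t, yy: rhs(yy, q)
        sol = solve_ivp(f, (a, b), y, method="LSODA", rtol=RTOL, atol=ATOL,
                        t_eval=t_eval if len(t_eval) else None)
        if not sol.success:
            raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else a)
        if len(t_eval):
            times.append(sol.t)
            states.append(sol.y.T)
        # always continue from the segment end state
        end = solve_ivp(f, (sol.t[-1], b), sol.y[:, -1], method="LSODA",
                        rtol=RTOL, atol=ATOL) if sol.t[-1] < b else sol
        y = end.y[:, -1]

    time = np.concatenate(times)
    S = np.stack([s for s in np.concatenate(states, axis=0)])
    # numerical guard: clip tiny excursions outside the box
    S = np.clip(S, 0.0, totals[None, :])
    stress_arr = np.array([protocol.stress_at(t) for t in time])
    q_end = p.with_stress(protocol.stress_at(protocol.horizon))
    settled = bool(np.max(np.abs(rhs(S[-1], q_end))) < SETTLE_TOL)
    return Trajectory(time=time, states=S, stress=stress_arr,
                      events=tuple(t for t, _ in protocol.schedule[1:]),
                      protocol=protocol, params=p, settled=settled)


def commitment_time(params: ParameterSet = DEFAULT_PARAMS, stress: float = 40.0,
                    frac: float = 0.9) -> float:
    """First time the apoptosis inducer exceeds ``frac`` of its high branch.

    The high-branch value is taken from the steady-state finder at the given
    stress; raises if no death branch exists there.
    """
    from .bifurcation import find_steady_states
    half = 0.5 * params.AT_apop
    highs = [s.apop for s in find_steady_states(params, stress) if s.stable and s.apop >= half]
    if not highs:
        raise ValueError(f"no stable death branch at stress {stress}")
    target = frac * max(highs)
    traj = integrate(params, Protocol(schedule=((0.0, stress),), horizon=DEFAULT_HORIZON,
                                      name="commitment-probe"))
    above = np.nonzero(traj.series("apop") >= target)[0]
    if not len(above):
        raise ValueError("apoptosis never reaches the commitment level within the horizon")
    return float(traj.time[above[0]])


def _washout_protocol(params: ParameterSet) -> Protocol:
    t_wash = commitment_time(params) + 5.0
    return Protocol(schedule=((0.0, 40.0), (t_wash, 0.0)), horizon=2 * DEFAULT_HORIZON,
                    name="washout")


#: scenario registry: name -> Protocol factory (params -> Protocol)
SCENARIOS = {
    "low_stress": lambda p: Protocol(schedule=((0.0, 25.0),), name="low_stress"),
    "high_stress": lambda p: Protocol(schedule=((0.0, 40.0),), name="high_stress"),
    "siPERK_high_stress": lambda p: Protocol(schedule=((0.0, 40.0),), preset="siPERK",
                                             name="siPERK_high_stress"),
    "IRE1low_high_stress": lambda p: Protocol(schedule=((0.0, 40.0),), preset="IRE1-inhibited",
                                              name="IRE1low_high_stress"),
    "washout": _washout_protocol,
}


def run_scenario(name: str, params: ParameterSet = DEFAULT_PARAMS) -> Trajectory:
    """Integrate one of the registered experimental scenarios."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    return integrate(params, SCENARIOS[name](params))
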