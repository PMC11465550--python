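"""Numerical simulation of OdeModel trajectories.

The symbolic right-hand side and output map are compiled once per model
(with known constants substituted numerically) and integrated with a
stiff-capable adaptive solver (LSODA) at tight tolerances; the outputs are
evaluated from the state trajectory via g.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .model import TIME, OdeModel, parameter_point

__all__ = ["Trajectory", "simulate", "SimulationError"]

#: default integrator tolerances (configurable per call)
RTOL = 1e-8
ATOL = 1e-10


class SimulationError(RuntimeError):
    """Integration failure, carrying the time at which it occurred."""


class _Diverged(Exception):
    """Internal: integration aborted because a state left bounds."""


@dataclass
class Trajectory:
    """Simulated time courses of states and outputs.

    ``states`` is (n_times, n_states); ``outputs`` maps observable id to a
    1-d array over the same times.
    """

    times: np.ndarray
    states: np.ndarray
    outputs: dict
    state_names: tuple
    model_name: str = ""

    def output(self, name: str) -> np.ndarray:
        return self.outputs[name]

    def as_frame(self) -> pd.DataFrame:
        data = {"time": self.times}
        for i, s in enumerate(self.state_names):
            data[f"state:{s}"] = self.states[:, i]
        for name, vals in self.outputs.items():
            data[f"output:{name}"] = vals
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)


@lru_cache(maxsize=64)
def _compiled(model: OdeModel):
    """Compile rhs f(t, x, p) and outputs g(t, x, p) to numpy callables."""
    const_subs = model.substituted_constants(exact=False)
    x = list(model.states)
    p = list(model.unknowns)
    rhs = [f.xreplace(const_subs) for f in model.rhs]
    outs = {k: g.xreplace(const_subs) for k, g in model.outputs.items()}
    args = (TIME, x, p)
    f_fun = sp.lambdify(args, rhs, modules="numpy", cse=True)
    g_fun = sp.lambdify(args, list(outs.values()), modules="numpy", cse=True)
    return f_fun, g_fun, tuple(outs)


def _initial_state(model: OdeModel, point: Mapping) -> np.ndarray:
    x0 = []
    for s in model.states:
        v = model.init[s]
        x0.append(point[v] if isinstance(v, sp.Symbol) else float(v))
    return np.asarray(x0, dtype=float)


def simulate(
    model: OdeModel,
    params: Mapping,
    times: Sequence[float],
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the model IVP and evaluate the outputs at ``times``.

    ``times`` must be ordered and start at (or after) t0 = 0; the first
    row of the trajectory at t0 equals the initial conditions exactly.
    """
    point = parameter_point(model, params)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    if times[0] < 0:
        raise ValueError("times must start at or after t0 = 0")

    f_fun, g_fun, out_names = _compiled(model)
    pvec = np.array([point[s] for s in model.unknowns], dtype=float)
    x0 = _initial_state(model, point)

    if model.n_states == 0:
        states = np.zeros((len(times), 0))
    elif len(times) == 1 and times[0] == 0.0:
        states = x0[None, :]
    else:
        t0 = 0.0
        blown = []

        def rhs(t, x):
            # divergence guard: a finite-time blow-up otherwise drives the
            # step-size controller into an unbounded shrink loop
            if not np.all(np.abs(x) < 1e100):
                blown.append(t)
                raise _Diverged(t)
            return np.asarray(f_fun(t, x, pvec), dtype=float)

        try:
            sol = solve_ivp(
                rhs,
                (t0, float(times[-1])),
                x0,
                method="LSODA",
                t_eval=times,
                rtol=rtol,
                atol=atol,
            )
        except _Diverged:
            raise SimulationError(
                f"state of {model.name} diverged near t = {blown[-1]:.6g}"
            ) from None
        if not sol.success:
            t_fail = sol.t[-1] if len(sol.t) else t0
            raise SimulationError(
                f"integration of {model.name} failed near t = {t_fail:.6g}: {sol.message}"
            )
        states = sol.y.T
        if not np.all(np.isfinite(states)):
            bad = np.where(~np.isfinite(states).all(axis=1))[0][0]
            raise SimulationError(
                f"non-finite state in {model.name} at t = {times[bad]:.6g}"
            )
        # exact ICs at t0 (solve_ivp returns them unmodified, but be explicit)
        if times[0] == t0:
            states[0] = x0

    outputs_rows = np.empty((len(times), len(out_names)), dtype=float)
    for i, (t, x) in enumerate(zip(times, states)):
        outputs_rows[i] = np.asarray(g_fun(t, x, pvec), dtype=float)
    outputs = {name: outputs_rows[:, j] for j, name in enumerate(out_names)}
    return Trajectory(
        times=times,
        states=states,
        outputs=outputs,
        state_names=tuple(str(s) for s in model.states),
        model_name=model.name,
    )
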