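"""Maximum-likelihood (weighted least-squares) estimation for ODE models.

Under additive Gaussian noise with standard deviation sigma per record the
negative log-likelihood equals, up to an additive constant, the chi-square
objective

    J(p) = sum_i ((y_obs_i - y_sim_i(p)) / sigma_i)^2 ,

which is what every routine here minimises and reports (the -2 log L
scale, so profile-likelihood thresholds add chi-square quantiles
directly).  When sigmas are absent a constant per-observable sigma is
profiled out analytically (sigma_hat^2 = mean squared residual) with the
corresponding log-term retained.

Parameters are optimised on the log scale by default — every parameter in
the bundled bioprocess models is a positive rate or constant.

The statsmodels-style front end is :class:`OdeMLE` (model + data) whose
``fit`` returns :class:`OdeMLEResults` with ``profile``/``profile_all``/
``summary``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .model import Dataset, ModelError, OdeModel
from .simulate import ATOL, RTOL, SimulationError, simulate

__all__ = ["objective", "fit", "FitResult", "FitError", "OdeMLE", "OdeMLEResults"]

FIT_TOL = 1e-8


class FitError(RuntimeError):
    """All optimisation starts failed; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


def _predictions(model: OdeModel, params: Mapping, data: Dataset, rtol, atol) -> np.ndarray:
    """Simulated value for each data record (one integration pass)."""
    df = data.frame
    times = np.unique(np.concatenate(([0.0], df["time"].to_numpy())))
    traj = simulate(model, params, times, rtol=rtol, atol=atol)
    index = {t: i for i, t in enumerate(traj.times)}
    pred = np.empty(len(df))
    for k, (tv, obs) in enumerate(zip(df["time"].to_numpy(), df["observable"])):
        pred[k] = traj.outputs[obs][index[tv]]
    return pred


def residual_table(model, params, data, rtol=RTOL, atol=ATOL) -> pd.DataFrame:
    df = data.frame.copy()
    df["predicted"] = _predictions(model, params, data, rtol, atol)
    df["residual"] = df["value"] - df["predicted"]
    return df


def objective(
    model: OdeModel,
    params: Mapping,
    data: Dataset,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> float:
    """Chi-square (-2 log L up to a constant) of the model against the data.

    Records with a sigma contribute ``((y_obs - y_sim)/sigma)^2``; for
    observables recorded without sigma a constant noise level is profiled
    out per observable (contribution ``n * log(sigma_hat^2) + n`` with
    ``sigma_hat^2`` the mean squared residual).
    """
    data.validate_against(model)
    df = residual_table(model, params, data, rtol, atol)
    have = df["sigma"].notna()
    total = float(np.sum((df.loc[have, "residual"] / df.loc[have, "sigma"]) ** 2))
    rest = df.loc[~have]
    for _, grp in rest.groupby("observable"):
        n = len(grp)
        s2 = float(np.mean(grp["residual"] ** 2))
        total += n * math.log(max(s2, 1e-300)) + n
    return total


@dataclass
class FitResult:
    """Best multi-start weighted least-squares estimate.

    ``objective`` is on the -2 log L (chi-square) scale; ``residuals`` is
    the record table with predicted values and residuals at the optimum.
    """

    estimate: dict
    objective: float
    residuals: pd.DataFrame
    success: bool
    n_starts: int
    start_objectives: list = field(default_factory=list)
    fixed: dict = field(default_factory=dict)
    message: str = ""
    bounds: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def full_point(self) -> dict:
        """Estimate plus any fixed parameters (a complete ParameterPoint)."""
        point = dict(self.fixed)
        point.update(self.estimate)
        return point


def _default_bounds(init: Mapping[str, float]) -> dict:
    return {k: (abs(v) * 1e-3 if v else 1e-6, max(abs(v), 1e-6) * 1e3) for k, v in init.items()}


def fit(
    model: OdeModel,
    data: Dataset,
    init: Mapping,
    bounds: Optional[Mapping] = None,
    n_starts: int = 1,
    seed: Optional[int] = None,
    fixed: Optional[Mapping] = None,
    log_scale: bool = True,
    rtol: float = RTOL,
    atol: float = ATOL,
    tol: float = FIT_TOL,
) -> FitResult:
    """Multi-start local least squares against a time-course dataset.

    The first start is ``init``; the remaining ``n_starts - 1`` are drawn
    log-uniformly within ``bounds`` (default: a factor of 1000 either side
    of the initial guess).  ``fixed`` pins a subset of unknowns at given
    values (the mechanism profile likelihood uses for the profiled
    parameter).  Deterministic given (data, init, bounds, n_starts, seed).
    """
    data.validate_against(model)
    fixed = {str(k): float(v) for k, v in (fixed or {}).items()}
    all_names = [str(u) for u in model.unknowns]
    for k in fixed:
        if k not in all_names:
            raise ModelError(f"fixed parameter '{k}' is not an unknown of {model.name}")
    free = [n for n in all_names if n not in fixed]
    if not free:
        raise ModelError("no free parameters left to fit")
    init = {str(k): float(v) for k, v in init.items() if str(k) in free}
    missing = [n for n in free if n not in init]
    if missing:
        raise ModelError(f"initial guess missing parameter(s): {missing}")

    bounds = {str(k): tuple(map(float, v)) for k, v in (bounds or {}).items()}
    full_bounds = _default_bounds(init)
    full_bounds.update({k: v for k, v in bounds.items() if k in free})
    lo = np.array([full_bounds[n][0] for n in free])
    hi = np.array([full_bounds[n][1] for n in free])
    if np.any(lo >= hi) or not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ModelError("bounds must be finite with lower < upper")
    x_init = np.array([init[n] for n in free])
    x_init = np.clip(x_init, lo, hi)
    if log_scale and np.any(lo <= 0):
        raise ModelError("log-scale optimisation requires positive lower bounds")

    def encode(x):
        return np.log(x) if log_scale else np.asarray(x, dtype=float)

    def decode(z):
        return np.exp(z) if log_scale else np.asarray(z, dtype=float)

    zlo, zhi = encode(lo), encode(hi)

    use_ls = data.has_sigma
    df = data.frame
    w_sigma = df["sigma"].to_numpy(dtype=float) if use_ls else None
    y_obs = df["value"].to_numpy(dtype=float)

    def point_of(z) -> dict:
        vals = decode(z)
        point = dict(fixed)
        point.update({n: v for n, v in zip(free, vals)})
        return point

    def ls_residuals(z):
        try:
            pred = _predictions(model, point_of(z), data, rtol, atol)
        except SimulationError:
            return np.full(len(y_obs), 1e6)
        r = (y_obs - pred) / w_sigma
        return np.where(np.isfinite(r), r, 1e6)

    def scalar_objective(z):
        try:
            return objective(model, point_of(z), data, rtol=rtol, atol=atol)
        except SimulationError:
            return 1e12

    rng = np.random.default_rng(seed)
    starts = [encode(x_init)]
    for _ in range(max(0, int(n_starts) - 1)):
        if log_scale:
            starts.append(rng.uniform(zlo, zhi))
        else:
            starts.append(np.exp(rng.uniform(np.log(np.maximum(lo, 1e-12)), np.log(hi))))

    best = None
    diagnostics = []
    for z0 in starts:
        try:
            if use_ls:
                res = least_squares(
                    ls_residuals,
                    z0,
                    bounds=(zlo, zhi),
                    method="trf",
                    xtol=tol,
                    ftol=tol,
                    gtol=tol,
                )
                obj = float(np.sum(res.fun**2))
                ok = bool(res.success)
                msg = res.message
                zhat = res.x
            else:
                res = minimize(
                    scalar_objective,
                    z0,
                    method="L-BFGS-B",
                    bounds=list(zip(zlo, zhi)),
                    options={"ftol": tol, "gtol": 1e-6},
                )
                obj = float(res.fun)
                ok = bool(res.success)
                msg = str(res.message)
                zhat = res.x
        except Exception as exc:  # per-start diagnostics, never abort the sweep
            diagnostics.append({"start": decode(z0).tolist(), "error": str(exc)})
            continue
        diagnostics.append({"start": decode(z0).tolist(), "objective": obj, "success": ok})
        if best is None or obj < best[0]:
            best = (obj, zhat, ok, msg)

    if best is None:
        raise FitError("all optimisation starts failed", diagnostics)

    obj, zhat, ok, msg = best
    estimate = {n: float(v) for n, v in zip(free, decode(zhat))}
    point = dict(fixed)
    point.update(estimate)
    return FitResult(
        estimate=estimate,
        objective=obj,
        residuals=residual_table(model, point, data, rtol, atol),
        success=ok,
        n_starts=len(starts),
        start_objectives=[d.get("objective") for d in diagnostics],
        fixed=fixed,
        message=msg,
        bounds={n: (float(full_bounds[n][0]), float(full_bounds[n][1])) for n in free},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------

class OdeMLE:
    """Maximum-likelihood estimation of ODE parameters from time courses.

    Construct from a validated :class:`~odeident.model.OdeModel` and a
    :class:`~odeident.model.Dataset`; ``fit`` returns
    :class:`OdeMLEResults` carrying the estimates and the profiling /
    summary machinery.
    """

    def __init__(self, model: OdeModel, data: Dataset):
        data.validate_against(model)
        self.model = model
        self.data = data

    @classmethod
    def from_files(cls, model_path, data_path) -> "OdeMLE":
        from .model import load_model

        return cls(load_model(model_path), Dataset.from_csv(data_path))

    def simulate(self, params: Mapping, times: Sequence[float]):
        return simulate(self.model, params, times)

    def objective(self, params: Mapping) -> float:
        return objective(self.model, params, self.data)

    def fit(
        self,
        init: Optional[Mapping] = None,
        bounds: Optional[Mapping] = None,
        n_starts: int = 1,
        seed: Optional[int] = None,
        **kwargs,
    ) -> "OdeMLEResults":
        if init is None:
            init = {str(u): 1.0 for u in self.model.unknowns}
        result = fit(
            self.model,
            self.data,
            init=init,
            bounds=bounds,
            n_starts=n_starts,
            seed=seed,
            **kwargs,
        )
        return OdeMLEResults(self, result)


class OdeMLEResults:
    """Fit results with profile-likelihood and summary methods."""

    def __init__(self, mle: OdeMLE, result: FitResult):
        self.model_obj = mle
        self.result = result

    # statsmodels-flavoured accessors ---------------------------------
    @property
    def params(self) -> dict:
        return dict(self.result.estimate)

    @property
    def objective(self) -> float:
        return self.result.objective

    @property
    def residuals(self) -> pd.DataFrame:
        return self.result.residuals

    def predict(self, times: Sequence[float]):
        return simulate(self.model_obj.model, self.result.full_point(), times)

    def profile(self, param: str, **options):
        from .profiling import profile_parameter

        return profile_parameter(
            self.model_obj.model, self.model_obj.data, self.result, param, **options
        )

    def profile_all(self, **options):
        from .profiling import profile_all

        return profile_all(self.model_obj.model, self.model_obj.data, self.result, **options)

    def summary(self) -> str:
        r = self.result
        lines = [
            f"OdeMLE results: {self.model_obj.model.name}",
            f"  records: {len(self.model_obj.data)}   "
            f"objective (-2 log L): {r.objective:.6g}   "
            f"starts: {r.n_starts}   converged: {r.success}",
            "  parameter        estimate",
        ]
        for name, v in r.estimate.items():
            lines.append(f"  {name:<15s} {v:>12.6g}")
        for name, v in r.fixed.items():
            lines.append(f"  {name:<15s} {v:>12.6g}  (fixed)")
        return "\n".join(lines)
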