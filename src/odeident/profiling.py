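"""Practical identifiability via the profile likelihood.

Each parameter in turn is stepped away from its maximum-likelihood
estimate on a grid; at every grid value the remaining (nuisance)
parameters are refitted.  The resulting profile objective is compared
with a chi-square threshold above the global minimum: the points where
the profile crosses the threshold bound a likelihood-ratio confidence
interval.  A parameter whose profile crosses on both sides is practically
identifiable; a flat or one-sided profile is practically unidentifiable
even when the model is structurally identifiable.

Threshold conventions (``df_convention``):

* ``pointwise`` (default): df = 1 — the standard per-parameter
  likelihood-ratio interval;
* ``residual``: df = n_obs - n_params — pairs the threshold with the
  residual degrees of freedom of the fit;
* ``simultaneous``: df = n_params — a joint confidence region projected
  per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .fitting import FIT_TOL, FitError, FitResult, fit
from .model import Dataset, OdeModel
from .simulate import ATOL, RTOL

__all__ = [
    "pl_threshold",
    "degrees_of_freedom",
    "profile_parameter",
    "profile_all",
    "classify_profile",
    "ProfileTrace",
    "ProfileSet",
]

IDENTIFIABLE = "practically identifiable"
UNIDENTIFIABLE = "practically unidentifiable"


def degrees_of_freedom(n_obs: int, n_params: int, convention: str = "pointwise") -> int:
    """Degrees of freedom for the chi-square threshold quantile.

    ``residual`` gives n_obs - n_params (e.g. 10 observations and one
    free parameter give nine); ``pointwise`` is always 1; ``simultaneous``
    is n_params.
    """
    if convention == "pointwise":
        return 1
    if convention == "simultaneous":
        if n_params < 1:
            raise ValueError("simultaneous convention needs n_params >= 1")
        return int(n_params)
    if convention == "residual":
        df = int(n_obs) - int(n_params)
        if df <= 0:
            raise ValueError(
                f"residual convention needs n_obs > n_params (got {n_obs}, {n_params})"
            )
        return df
    raise ValueError(f"unknown df convention '{convention}'")


def pl_threshold(objective_min: float, df: int, alpha: float = 0.05) -> float:
    """Profile-likelihood threshold on the -2 log L scale.

    ``objective_min + chi2.ppf(1 - alpha, df)``; crossing it bounds the
    (1 - alpha) likelihood-ratio confidence interval.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if int(df) < 1:
        raise ValueError("df must be a positive integer")
    return float(objective_min) + float(chi2.ppf(1.0 - alpha, int(df)))


@dataclass
class ProfileTrace:
    """Profile-likelihood trace of one parameter.

    ``grid``/``objective`` are sorted ascending in the parameter and
    include the MLE point; ``lower``/``upper`` are interpolated threshold
    crossings, or None with a status ("bound", "max-steps", "flat")
    naming why that side never crossed.
    """

    param: str
    grid: np.ndarray
    objective: np.ndarray
    nuisance: list
    mle_value: float
    mle_objective: float
    threshold: float
    lower: Optional[float]
    upper: Optional[float]
    lower_status: str
    upper_status: str
    alpha: float
    df: int
    flat: bool = False
    failed_points: list = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return classify_profile(self)

    @property
    def identifiable(self) -> bool:
        return self.lower is not None and self.upper is not None

    def ci(self) -> tuple:
        return (self.lower, self.upper)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"value": self.grid, "objective": self.objective})
        nuisance_names = sorted({k for n in self.nuisance for k in n})
        for name in nuisance_names:
            df[f"nuisance:{name}"] = [n.get(name, np.nan) for n in self.nuisance]
        return df

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "param": self.param,
            "mle": self.mle_value,
            "threshold": self.threshold,
            "alpha": self.alpha,
            "df": self.df,
            "lower": self.lower,
            "upper": self.upper,
            "lower_status": self.lower_status,
            "upper_status": self.upper_status,
            "flat": self.flat,
            "verdict": self.verdict,
        }


def classify_profile(trace: ProfileTrace) -> str:
    """Identifiable iff the threshold is crossed on both sides of the MLE."""
    return IDENTIFIABLE if trace.identifiable else UNIDENTIFIABLE


def _interp_crossing(p0, f0, p1, f1, threshold) -> float:
    if f1 == f0:
        return p1
    return p0 + (threshold - f0) * (p1 - p0) / (f1 - f0)


def profile_parameter(
    model: OdeModel,
    data: Dataset,
    fit_result: FitResult,
    param: str,
    alpha: float = 0.05,
    df_convention: str = "pointwise",
    max_steps: int = 100,
    init_step_frac: float = 0.01,
    target_frac: float = 0.1,
    flat_tol: float = 0.01,
    refit_tol: float = 1e-3,
    n_starts: int = 1,
    rtol: float = RTOL,
    atol: float = ATOL,
    tol: float = FIT_TOL,
) -> ProfileTrace:
    """Profile one parameter with nuisance reoptimisation.

    Stepping is adaptive: the initial step is ``init_step_frac`` of |MLE|
    (or 0.01 when the MLE is ~0) and is rescaled so each step raises the
    objective by roughly ``target_frac`` of the chi-square increment,
    clamped to [1e-4, 0.5] x |MLE|.  Each nuisance refit is warm-started
    from its neighbour, with a cold-start retry whenever a refit lands
    more than one threshold increment above its neighbour.  A direction
    stops on threshold crossing, on hitting the parameter bound, or after
    ``max_steps`` steps; crossings are interpolated linearly between the
    bracketing grid points.
    """
    param = str(param)
    if param not in fit_result.estimate:
        raise ValueError(f"'{param}' is not a free parameter of the fit")
    if not fit_result.success:
        raise ValueError("profiling requires a converged fit")

    estimate = dict(fit_result.estimate)
    mle = estimate[param]
    free_names = [n for n in estimate if n != param]
    n_free = len(fit_result.estimate)
    df = degrees_of_freedom(len(data), n_free, df_convention)
    quantile = pl_threshold(0.0, df, alpha)
    threshold = fit_result.objective + quantile

    bounds = dict(fit_result.bounds)
    pb_lo, pb_hi = bounds.get(param, (mle * 1e-3 if mle > 0 else 1e-9, abs(mle) * 1e3 + 1.0))
    nuis_bounds = {n: bounds[n] for n in free_names if n in bounds}

    def refit(value, warm_init) -> tuple:
        """(objective, nuisance estimates) with param fixed at value."""
        fixed = dict(fit_result.fixed)
        fixed[param] = value
        if not free_names:
            from .fitting import objective as obj_fun

            point = dict(fixed)
            return obj_fun(model, point, data, rtol=rtol, atol=atol), {}
        res = fit(
            model,
            data,
            init=warm_init,
            bounds=nuis_bounds,
            fixed=fixed,
            n_starts=n_starts,
            seed=0,
            rtol=rtol,
            atol=atol,
            tol=tol,
        )
        return res.objective, dict(res.estimate)

    # consistency refit at the MLE: must reproduce the global optimum
    warm0 = {n: estimate[n] for n in free_names}
    obj0, nuis0 = refit(mle, warm0)
    if obj0 > fit_result.objective + max(refit_tol * (1 + abs(fit_result.objective)), 1e-6):
        raise RuntimeError(
            f"refit at the MLE gives {obj0:.6g} vs fitted {fit_result.objective:.6g}; "
            "the supplied fit is not at a (local) optimum"
        )
    obj0 = min(obj0, fit_result.objective)

    base_step = init_step_frac * abs(mle) if abs(mle) > 1e-12 else 0.01
    min_step = max(1e-4 * abs(mle), 1e-12)
    max_step = max(0.5 * abs(mle), 10 * base_step)
    target_inc = target_frac * quantile

    points = {mle: (obj0, nuis0)}
    failed: list = []
    sides = {}
    for direction in (-1.0, +1.0):
        step = base_step
        p_prev, f_prev = mle, obj0
        warm = dict(nuis0) if nuis0 else {}
        crossing = None
        status = "max-steps"
        for _ in range(max_steps):
            p_new = p_prev + direction * step
            at_bound = False
            if direction < 0 and p_new <= pb_lo:
                p_new, at_bound = pb_lo, True
            elif direction > 0 and p_new >= pb_hi:
                p_new, at_bound = pb_hi, True
            try:
                f_new, nuis = refit(p_new, warm if warm else warm0)
                if f_new > f_prev + quantile and free_names:
                    # suspicious jump: cold-start retry from the global MLE
                    f_retry, nuis_retry = refit(p_new, warm0)
                    if f_retry < f_new:
                        f_new, nuis = f_retry, nuis_retry
            except (FitError, RuntimeError) as exc:
                failed.append({"value": p_new, "error": str(exc)})
                p_prev = p_new
                continue
            points[p_new] = (f_new, nuis)
            if f_new >= threshold:
                crossing = _interp_crossing(p_prev, f_prev, p_new, f_new, threshold)
                status = "crossed"
                break
            if at_bound:
                status = "bound"
                break
            delta = f_new - f_prev
            if delta < 0.2 * target_inc:
                step = min(step * 2.0, max_step)
            elif delta > 2.0 * target_inc:
                step = max(step * 0.5, min_step)
            if warm is not None:
                warm = dict(nuis) if nuis else {}
            p_prev, f_prev = p_new, f_new
        sides[direction] = (crossing, status)

    grid = np.array(sorted(points))
    objective_vals = np.array([points[p][0] for p in grid])
    nuisance = [points[p][1] for p in grid]
    flat = bool(np.max(objective_vals) - np.min(objective_vals) < flat_tol * quantile)

    lower, lower_status = sides[-1.0]
    upper, upper_status = sides[+1.0]
    if flat:
        lower = upper = None
        lower_status = upper_status = "flat"

    return ProfileTrace(
        param=param,
        grid=grid,
        objective=objective_vals,
        nuisance=nuisance,
        mle_value=mle,
        mle_objective=obj0,
        threshold=threshold,
        lower=lower,
        upper=upper,
        lower_status=lower_status,
        upper_status=upper_status,
        alpha=alpha,
        df=df,
        flat=flat,
        failed_points=failed,
    )


@dataclass
class ProfileSet:
    """Profile traces for every free parameter plus the model-level verdict."""

    traces: dict
    alpha: float
    df_convention: str

    @property
    def model_verdict(self) -> str:
        ok = all(t.identifiable for t in self.traces.values())
        return IDENTIFIABLE if ok else UNIDENTIFIABLE

    @property
    def unidentifiable_params(self) -> list:
        return [p for p, t in self.traces.items() if not t.identifiable]

    def __getitem__(self, param: str) -> ProfileTrace:
        return self.traces[param]

    def __iter__(self):
        return iter(self.traces.values())

    def summary(self) -> str:
        lines = [
            f"Profile likelihood ({100 * (1 - self.alpha):g}% CI, "
            f"{self.df_convention} convention)",
            "  parameter        estimate        lower        upper  verdict",
        ]
        for p, t in self.traces.items():
            lo = f"{t.lower:.6g}" if t.lower is not None else f"({t.lower_status})"
            hi = f"{t.upper:.6g}" if t.upper is not None else f"({t.upper_status})"
            lines.append(
                f"  {p:<15s} {t.mle_value:>12.6g} {lo:>12s} {hi:>12s}  {t.verdict}"
            )
        lines.append(f"  model: {self.model_verdict}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "df_convention": self.df_convention,
            "parameters": {p: t.to_dict() for p, t in self.traces.items()},
            "model_verdict": self.model_verdict,
            "unidentifiable": self.unidentifiable_params,
        }


def profile_all(
    model: OdeModel,
    data: Dataset,
    fit_result: FitResult,
    params: Optional[list] = None,
    alpha: float = 0.05,
    df_convention: str = "pointwise",
    **options,
) -> ProfileSet:
    """Profile every free parameter (or the named subset).

    The model is practically identifiable iff every profiled parameter
    has a finite two-sided confidence interval.  Per-parameter failures
    are aggregated and re-raised together.
    """
    names = list(params) if params else list(fit_result.estimate)
    traces = {}
    errors = {}
    for name in names:
        try:
            traces[name] = profile_parameter(
                model,
                data,
                fit_result,
                name,
                alpha=alpha,
                df_convention=df_convention,
                **options,
            )
        except Exception as exc:
            errors[name] = exc
    if errors:
        detail = "; ".join(f"{p}: {e}" for p, e in errors.items())
        raise RuntimeError(f"profiling failed for {len(errors)} parameter(s): {detail}")
    return ProfileSet(traces=traces, alpha=alpha, df_convention=df_convention)
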