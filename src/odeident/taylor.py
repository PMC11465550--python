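"""Taylor-series structural identifiability analysis.

The observed outputs are expanded in a Taylor series about the initial time
t0 = 0.  Every derivative coefficient y^(k)(0) is, by assumption, a known
measurable quantity; the coefficients are polynomial (or algebraic)
expressions in the unknown parameters, so solving the coefficient system
tells us whether each parameter has a unique solution (globally
identifiable), finitely many (locally identifiable) or infinitely many
(structurally unidentifiable).

Successive output derivatives are generated with the Lie derivative along
the vector field f:  D(h) = sum_i (dh/dx_i) f_i + dh/dt.
"""

from __future__ import annotations

import signal
import threading
from contextlib import contextmanager
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import sympy as sp

from .model import TIME, OdeModel, to_exact

__all__ = [
    "lie_derivative",
    "output_derivatives",
    "taylor_coefficients",
    "TaylorCoefficients",
    "coefficient_cap",
    "classify_taylor",
    "SiaVerdict",
    "ParamClass",
    "SolveTimeout",
]


def lie_derivative(model: OdeModel, expr: sp.Expr) -> sp.Expr:
    """Time derivative of ``expr(x, t)`` along the model's vector field."""
    d = sp.S.Zero
    for x, f in zip(model.states, model.rhs):
        d += sp.diff(expr, x) * f
    d += sp.diff(expr, TIME)
    return d


def output_derivatives(model: OdeModel, order: int) -> dict:
    """Output time derivatives d^k y/dt^k for k = 0..order, per output.

    Entries are expressions in the states and parameters (known constants
    substituted exactly); entry 0 is the output expression itself.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    const_subs = model.substituted_constants(exact=True)
    derivs: dict = {}
    for name, g in model.outputs.items():
        seq = [g.xreplace(const_subs)]
        rhs_sub = [f.xreplace(const_subs) for f in model.rhs]
        sub_model = _with_rhs(model, rhs_sub)
        for _ in range(order):
            seq.append(lie_derivative(sub_model, seq[-1]))
        derivs[name] = seq
    return derivs


def _with_rhs(model: OdeModel, rhs) -> OdeModel:
    # lightweight internal clone used to carry constant-substituted rhs
    clone = object.__new__(OdeModel)
    object.__setattr__(clone, "__dict__", dict(model.__dict__))
    object.__setattr__(clone, "rhs", tuple(rhs))
    return clone


@dataclass
class TaylorCoefficients:
    """Successive output derivatives evaluated at the expansion point t0.

    ``coefficients[name][k]`` is y_name^(k)(t0) as an expression in the
    unknown parameters (and any declared-unknown initial conditions).
    """

    coefficients: Mapping[str, Sequence[sp.Expr]]
    t0: float = 0.0
    model_name: str = ""

    def n_coefficients(self) -> int:
        return sum(len(v) for v in self.coefficients.values())

    def symbols(self) -> dict:
        """Fresh observed-coefficient symbols c_<output>_<k> per entry."""
        return {
            (name, k): sp.Symbol(f"c_{name}_{k}", real=True)
            for name, seq in self.coefficients.items()
            for k in range(len(seq))
        }


def coefficient_cap(model: OdeModel) -> tuple:
    """Taylor coefficient cap (2n - 1) and whether it is a strict bound.

    For systems linear in the states at most 2n - 1 coefficients are
    linearly independent, n being the state dimension; for nonlinear
    systems the same count is only a heuristic and is flagged non-strict.
    Returns ``(cap, strict)``.
    """
    n = model.n_states
    cap = max(2 * n - 1, 1)
    return cap, _linear_in_states(model)


def _linear_in_states(model: OdeModel) -> bool:
    if model.n_states == 0:
        return True
    const_subs = model.substituted_constants(exact=True)
    for f in model.rhs:
        f = f.xreplace(const_subs)
        try:
            poly = sp.Poly(sp.expand(f), *model.states)
        except sp.PolynomialError:
            return False
        if poly.total_degree() > 1:
            return False
    return True


def taylor_coefficients(
    model: OdeModel, n_coeffs: Optional[int] = None
) -> TaylorCoefficients:
    """Taylor coefficients y^(k)(0), k = 0..n_coeffs-1, per output.

    Initial conditions are substituted exactly (2.5 -> 5/2); unknown ICs
    stay symbolic.  Defaults to the 2n - 1 cap, which is a heuristic for
    models that are nonlinear in the states (pass ``n_coeffs`` explicitly
    to go higher).
    """
    if n_coeffs is None:
        n_coeffs, _ = coefficient_cap(model)
    if n_coeffs < 1:
        raise ValueError("n_coeffs must be positive")
    derivs = output_derivatives(model, n_coeffs - 1)
    ic_subs = {
        x: (v if isinstance(v, sp.Symbol) else to_exact(v))
        for x, v in model.init.items()
    }
    ic_subs[TIME] = sp.S.Zero
    coeffs = {
        name: [e.subs(ic_subs) for e in seq] for name, seq in derivs.items()
    }
    return TaylorCoefficients(coefficients=coeffs, t0=0.0, model_name=model.name)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class ParamClass(str, Enum):
    GLOBAL = "globally identifiable"
    LOCAL = "locally identifiable"
    UNIDENTIFIABLE = "unidentifiable"


@dataclass
class SiaVerdict:
    """Per-parameter structural identifiability classes and model verdict.

    ``overall`` is the weakest per-parameter class: a model is structurally
    identifiable only if every parameter is at least locally identifiable.
    ``status`` is "ok" or "inconclusive" (solver timeout — use the rank
    test instead).
    """

    per_parameter: dict
    solution_counts: dict
    real_solution_counts: dict
    overall: str
    n_coefficients_used: int
    status: str = "ok"
    message: str = ""
    solutions: list = field(default_factory=list)

    @property
    def identifiable(self) -> bool:
        return self.overall != ParamClass.UNIDENTIFIABLE.value and self.status == "ok"

    def summary(self) -> str:
        lines = [f"Taylor-series structural identifiability ({self.status})"]
        for p, cls in self.per_parameter.items():
            extra = ""
            if cls == ParamClass.LOCAL.value:
                extra = f" ({self.solution_counts[p]} solutions)"
            lines.append(f"  {p}: {cls}{extra}")
        lines.append(f"  overall: {self.overall}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": "taylor",
            "status": self.status,
            "per_parameter": dict(self.per_parameter),
            "solution_counts": dict(self.solution_counts),
            "real_solution_counts": dict(self.real_solution_counts),
            "overall": self.overall,
            "n_coefficients_used": self.n_coefficients_used,
            "message": self.message,
            "solutions": [
                {str(k): sp.sstr(v) for k, v in sol.items()} for sol in self.solutions
            ],
        }


class SolveTimeout(RuntimeError):
    pass


@contextmanager
def _time_limit(seconds: Optional[float]):
    # SIGALRM only works in the main thread; elsewhere run unbounded.
    usable = (
        seconds is not None
        and seconds > 0
        and hasattr(signal, "SIGALRM")
        and threading.current_thread() is threading.main_thread()
    )
    if not usable:
        yield
        return

    def _handler(signum, frame):
        raise SolveTimeout(f"symbolic solve exceeded {seconds} s")

    old = signal.signal(signal.SIGALRM, _handler)
    signal.setitimer(signal.ITIMER_REAL, float(seconds))
    try:
        yield
    finally:
        signal.setitimer(signal.ITIMER_REAL, 0.0)
        signal.signal(signal.SIGALRM, old)


def classify_taylor(
    coeffs: TaylorCoefficients,
    unknowns: Sequence[sp.Symbol],
    timeout: Optional[float] = 60.0,
) -> SiaVerdict:
    """Classify the unknown parameters from the Taylor coefficient system.

    The premise is that every output derivative at t0 is measurable and
    known, so an alternative parameter vector p* is indistinguishable
    from p exactly when every coefficient agrees: c_k(p*) = c_k(p).
    Solving that system for p* (always consistent — p* = p solves it)
    classifies each parameter:

    * p*_i forced to the single value p_i → globally identifiable;
    * finitely many branches, each free of other starred unknowns →
      locally identifiable (branch count kept, real-branch count too);
    * p*_i left free, or determined only up to other starred unknowns →
      structurally unidentifiable.

    A solver timeout yields status "inconclusive" (never a verdict) with a
    pointer to the rank test.
    """
    unknowns = tuple(unknowns)
    informative = [
        e
        for seq in coeffs.coefficients.values()
        for e in seq
        if e.free_symbols & set(unknowns)
    ]
    n_used = len(informative)
    empty = {str(p): ParamClass.UNIDENTIFIABLE.value for p in unknowns}
    if not informative:
        return SiaVerdict(
            per_parameter=empty,
            solution_counts={k: 0 for k in empty},
            real_solution_counts={k: 0 for k in empty},
            overall=ParamClass.UNIDENTIFIABLE.value,
            n_coefficients_used=0,
            message="no coefficient involves any unknown parameter",
        )
    starred = {p: sp.Symbol(f"{p}_alt", real=True) for p in unknowns}
    try:
        with _time_limit(timeout):
            # equation construction (cancellation of rational functions)
            # can itself be expensive, so it sits inside the time limit
            eqs = [sp.together(e.xreplace(starred) - e) for e in informative]
            sols = sp.solve(eqs, list(starred.values()), dict=True)
    except SolveTimeout as exc:
        return SiaVerdict(
            per_parameter={str(p): "inconclusive" for p in unknowns},
            solution_counts={},
            real_solution_counts={},
            overall="inconclusive",
            n_coefficients_used=n_used,
            status="inconclusive",
            message=f"{exc}; try the Jacobian rank test (sia-rank)",
        )
    if not sols:
        raise RuntimeError(
            "indistinguishability system returned no solutions, but p* = p "
            "always solves it — this indicates an internal error or an "
            "unsupported construct"
        )

    starred_set = set(starred.values())
    per: dict = {}
    counts: dict = {}
    real_counts: dict = {}
    for p in unknowns:
        ps = starred[p]
        branches = []
        free = False
        for sol in sols:
            if ps not in sol:
                free = True
                break
            expr = sp.simplify(sol[ps])
            if expr.free_symbols & starred_set:
                free = True  # tied to another indeterminate parameter
                break
            branches.append(expr)
        if free:
            per[str(p)] = ParamClass.UNIDENTIFIABLE.value
            counts[str(p)] = 0
            real_counts[str(p)] = 0
            continue
        distinct = _distinct_expressions(branches)
        counts[str(p)] = len(distinct)
        real_counts[str(p)] = _count_real(distinct, unknowns)
        per[str(p)] = (
            ParamClass.GLOBAL.value if len(distinct) == 1 else ParamClass.LOCAL.value
        )
    overall = _weakest(per.values())
    return SiaVerdict(
        per_parameter=per,
        solution_counts=counts,
        real_solution_counts=real_counts,
        overall=overall,
        n_coefficients_used=n_used,
        solutions=sols,
    )


def _distinct_expressions(exprs):
    distinct = []
    for e in exprs:
        if not any(sp.simplify(e - d) == 0 for d in distinct):
            distinct.append(e)
    return distinct


_GENERIC_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37)


def _count_real(exprs, unknowns) -> int:
    """Count branches real under a generic positive true-parameter point."""
    subs = {
        p: sp.Rational(_GENERIC_PRIMES[i % len(_GENERIC_PRIMES)], 7)
        for i, p in enumerate(unknowns)
    }
    n_real = 0
    for e in exprs:
        try:
            val = complex(sp.N(e.xreplace(subs)))
            if abs(val.imag) < 1e-9:
                n_real += 1
        except (TypeError, ValueError):
            n_real += 1  # could not evaluate; count as potentially real
    return n_real


def _weakest(classes) -> str:
    order = [
        ParamClass.UNIDENTIFIABLE.value,
        ParamClass.LOCAL.value,
        ParamClass.GLOBAL.value,
    ]
    for cls in order:
        if cls in classes:
            return cls
    return ParamClass.GLOBAL.value


def analyze_taylor(
    model: OdeModel,
    n_coeffs: Optional[int] = None,
    timeout: Optional[float] = 60.0,
) -> SiaVerdict:
    """One-call Taylor-series analysis: coefficients + classification."""
    coeffs = taylor_coefficients(model, n_coeffs=n_coeffs)
    return classify_taylor(coeffs, model.unknowns, timeout=timeout)
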