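"""Rank-based structural identifiability (exact-arithmetic Jacobian test).

Output time derivatives (Lie derivatives) up to some order are stacked and
differentiated with respect to the unknown parameters; the rank of the
resulting Jacobian at a generic point decides local structural
identifiability: full column rank means every parameter direction moves
some observable derivative, i.e. the model is at least locally
identifiable.  Rank deficiency gives the number of free directions
("degrees of freedom") in parameter space.

All rank computations use exact rational arithmetic at random rational
specializations of states and parameters, so there is no floating-point
rank ambiguity; several independent specializations guard against
measure-zero unlucky points.
"""

from __future__ import annotations

import itertools
import random
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import sympy as sp

from .model import OdeModel, to_exact
from .taylor import output_derivatives

__all__ = [
    "identifiability_jacobian",
    "rank_test",
    "RankResult",
    "suggest_known",
]


@dataclass
class RankResult:
    """Outcome of the Jacobian rank test.

    ``deficiency = n_unknowns - rank`` counts the parameter directions the
    outputs cannot see; zero deficiency means at least locally
    identifiable.
    """

    rank: int
    n_unknowns: int
    order: int
    trials: int
    seed: int
    unknowns: tuple = ()
    order_capped: bool = False

    def __post_init__(self):
        if not 0 <= self.rank <= self.n_unknowns:
            raise ValueError("rank must lie in [0, n_unknowns]")

    @property
    def deficiency(self) -> int:
        return self.n_unknowns - self.rank

    @property
    def verdict(self) -> str:
        return (
            "at-least-locally-identifiable"
            if self.deficiency == 0
            else "unidentifiable"
        )

    @property
    def identifiable(self) -> bool:
        return self.deficiency == 0

    def summary(self) -> str:
        return (
            f"Jacobian rank test: rank {self.rank} of {self.n_unknowns} unknowns "
            f"(order {self.order}, {self.trials} specializations) -> {self.verdict}"
            + (f" [{self.deficiency} degrees of freedom]" if self.deficiency else "")
        )

    def to_dict(self) -> dict:
        return {
            "method": "rank",
            "rank": self.rank,
            "n_unknowns": self.n_unknowns,
            "deficiency": self.deficiency,
            "verdict": self.verdict,
            "order": self.order,
            "order_capped": self.order_capped,
            "trials": self.trials,
            "seed": self.seed,
            "unknowns": [str(u) for u in self.unknowns],
        }


def identifiability_jacobian(
    model: OdeModel, order: int, substitute_init: bool = False
) -> sp.Matrix:
    """Symbolic Jacobian of stacked output derivatives w.r.t. the unknowns.

    Rows are all output derivatives of orders 0..order (states left
    symbolic, or replaced by the declared initial conditions when
    ``substitute_init`` — the fixed-IC variant can only lower the generic
    rank).  Columns are the unknown parameters plus any unknown ICs.
    """
    rows = _derivative_rows(model, order, substitute_init=substitute_init)
    unknowns = list(model.unknowns)
    return sp.Matrix([[sp.diff(r, p) for p in unknowns] for r in rows])


def _derivative_rows(model: OdeModel, order: int, substitute_init: bool = False):
    derivs = output_derivatives(model, order)
    rows = [e for seq in derivs.values() for e in seq]
    if substitute_init:
        ic = {
            x: (v if isinstance(v, sp.Symbol) else to_exact(v))
            for x, v in model.init.items()
        }
        rows = [r.subs(ic) for r in rows]
    return rows


def _random_rational(rng: random.Random) -> sp.Rational:
    # numerator/denominator uniform in 1..10^4: generic, exact, well scaled
    return sp.Rational(rng.randint(1, 10_000), rng.randint(1, 10_000))


def _specialized_rank(rows, unknowns, free_syms, rng: random.Random) -> int:
    # substituting generic rational state values before differentiating
    # w.r.t. the parameters is valid (states and parameters are independent
    # symbols in the derivative rows) and keeps expression swell down
    state_subs = {s: _random_rational(rng) for s in free_syms if s not in unknowns}
    rows_s = [r.xreplace(state_subs) for r in rows]
    jac = [[sp.diff(r, p) for p in unknowns] for r in rows_s]
    par_subs = {p: _random_rational(rng) for p in unknowns}
    mat = sp.Matrix([[sp.nsimplify(e.xreplace(par_subs)) for e in row] for row in jac])
    return mat.rank()


def rank_test(
    model: OdeModel,
    order: Union[int, str] = "auto",
    trials: int = 3,
    seed: int = 1,
    substitute_init: bool = False,
) -> RankResult:
    """Exact-arithmetic rank test over random rational specializations.

    The reported rank is the maximum over ``trials`` independent
    specializations (the generic rank is an upper bound attained off a
    measure-zero set, so the maximum is the right aggregator).  With
    ``order="auto"`` the derivative order grows until the rank is stable
    for two consecutive orders or reaches full column rank, capped at
    n_states + n_unknowns (a warning notes a cap hit before stability).
    """
    unknowns = list(model.unknowns)
    n_unknowns = len(unknowns)
    if n_unknowns == 0:
        return RankResult(0, 0, 0, trials, seed, unknowns=())
    cap = model.n_states + n_unknowns
    auto = order == "auto"
    if auto:
        orders = range(1, cap + 1)
    else:
        order = int(order)
        if order < 1:
            raise ValueError("order must be positive")
        orders = [order]

    best_rank = 0
    prev_rank = -1
    used_order = 0
    capped = False
    from .model import TIME

    for k in orders:
        rows = _derivative_rows(model, k, substitute_init=substitute_init)
        free = set().union(*(r.free_symbols for r in rows)) | set(unknowns)
        free.discard(TIME)
        rank_k = 0
        for trial in range(trials):
            rng = random.Random((seed, k, trial).__hash__() & 0x7FFFFFFF)
            rank_k = max(rank_k, _specialized_rank(rows, unknowns, free, rng))
            if rank_k == n_unknowns:
                break
        used_order = k
        if not auto:
            best_rank = rank_k
            break
        best_rank = max(best_rank, rank_k)
        if best_rank == n_unknowns or rank_k == prev_rank:
            break
        prev_rank = rank_k
    else:
        capped = True
        warnings.warn(
            f"derivative order cap {cap} reached before rank stabilized",
            stacklevel=2,
        )
    return RankResult(
        rank=best_rank,
        n_unknowns=n_unknowns,
        order=used_order,
        trials=trials,
        seed=seed,
        unknowns=tuple(unknowns),
        order_capped=capped,
    )


@dataclass
class KnownSetSuggestion:
    """Minimal parameter subsets whose prior knowledge restores full rank."""

    subsets: list
    complete: bool = True

    def __iter__(self):
        return iter(self.subsets)

    def to_dict(self) -> dict:
        return {
            "minimal_known_sets": [[str(p) for p in s] for s in self.subsets],
            "complete": self.complete,
        }


def suggest_known(
    model: OdeModel,
    max_subset: Optional[int] = None,
    order: Union[int, str] = "auto",
    trials: int = 3,
    seed: int = 1,
) -> KnownSetSuggestion:
    """All minimal parameter subsets to fix a rank-deficient model.

    Fixing a parameter to a known value removes its column from the
    identifiability Jacobian, so the search ranks column submatrices:
    a subset S is a fix when the columns of the remaining unknowns have
    full rank.  Exhaustive over subset sizes up to ``max_subset``
    (default: the rank deficiency bound n_unknowns - 1); intended for
    p <= 12 unknowns, beyond which results are flagged partial.
    """
    base = rank_test(model, order=order, trials=trials, seed=seed)
    if base.identifiable:
        return KnownSetSuggestion(subsets=[])
    unknowns = list(base.unknowns)
    n = len(unknowns)
    if max_subset is None:
        max_subset = n - 1
    complete = n <= 12

    rows = _derivative_rows(model, base.order)
    from .model import TIME

    free = set().union(*(r.free_symbols for r in rows)) | set(unknowns)
    free.discard(TIME)

    # precompute specialized Jacobians once per trial; subsets reuse columns
    mats = []
    for trial in range(trials):
        rng = random.Random((seed, base.order, trial).__hash__() & 0x7FFFFFFF)
        state_subs = {s: _random_rational(rng) for s in free if s not in unknowns}
        rows_s = [sp.cancel(r.xreplace(state_subs)) for r in rows]
        jac = [[sp.diff(r, p) for p in unknowns] for r in rows_s]
        par_subs = {p: _random_rational(rng) for p in unknowns}
        mats.append(
            sp.Matrix(
                [[sp.nsimplify(e.xreplace(par_subs), rational=True) for e in row] for row in jac]
            )
        )

    def remaining_full_rank(subset) -> bool:
        keep = [i for i, p in enumerate(unknowns) if p not in subset]
        if not keep:
            return True
        need = len(keep)
        return any(m[:, keep].rank() == need for m in mats)

    minimal: list = []
    search_sizes = range(1, min(max_subset, n) + 1)
    for size in search_sizes if complete else list(search_sizes)[:2]:
        for combo in itertools.combinations(unknowns, size):
            subset = set(combo)
            if any(s <= subset for s in map(set, minimal)):
                continue  # superset of an already-minimal fix
            if remaining_full_rank(subset):
                minimal.append(tuple(combo))
        if minimal and size >= max(len(s) for s in minimal):
            break
    return KnownSetSuggestion(subsets=minimal, complete=complete)
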