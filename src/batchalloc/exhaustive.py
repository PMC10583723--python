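"""Exhaustive enumeration of binary remainder allocations.

For small instances the optimum can be found by brute force: enumerate
every feasible 0/1 remainder matrix with the required row and column
sums and keep the best D-criterion score.  The search space grows as
``prod_k C(T, b*_k)``, so enumeration is guarded by a budget cap; beyond
desk scale the stochastic heuristic is the only practical option.

Batches of equal size are interchangeable before the post-hoc batch
order randomization, and the D-criterion is invariant to row
permutations, so consecutive equal-capacity batches are enumerated in
nondecreasing lexicographic order — each distinct design is visited once
instead of once per reordering.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterator

import numpy as np

from .errors import BudgetExceededError
from .prealloc import preallocate
from .problem import AllocationProblem
from .scoring import ScoredAllocation, d_criterion

__all__ = [
    "search_space_size",
    "enumerate_allocations",
    "optimal_allocation",
    "all_subsets_incidence",
]

DEFAULT_MAX_SPACE = 10_000_000


def search_space_size(problem: AllocationProblem) -> int:
    """Upper bound ``prod_k C(T, b*_k)`` on the number of remainder allocations.

    Computed after preallocation; an overestimate (it ignores the column
    sum constraints) but a standard proxy for enumeration cost.
    """
    pre = preallocate(problem)
    T = problem.n_treatments
    size = 1
    for cap in pre.b_star:
        size *= comb(T, int(cap))
    return size


def enumerate_allocations(
    problem: AllocationProblem, max_space: int = DEFAULT_MAX_SPACE
) -> Iterator[np.ndarray]:
    """Yield every feasible completed incidence matrix exactly once
    (up to reordering of consecutive equal-sized batches).

    Each yielded matrix is the preallocated quota plus a binary remainder
    with column sums ``t*`` and row sums ``b*``.

    Raises
    ------
    BudgetExceededError
        If :func:`search_space_size` exceeds ``max_space``.
    """
    space = search_space_size(problem)
    if space > max_space:
        raise BudgetExceededError(
            f"search space {space} exceeds budget cap {max_space}"
        )
    pre = preallocate(problem)
    B = problem.n_batches
    T = problem.n_treatments
    caps = [int(c) for c in pre.b_star]
    t_star = [int(x) for x in pre.t_star]
    N = np.zeros((B, T), dtype=int)

    def rec(k: int, prev_row: tuple[int, ...] | None) -> Iterator[np.ndarray]:
        if k == B:
            if all(x == 0 for x in t_star):
                yield pre.N_star + N
            return
        cap = caps[k]
        remaining = B - k
        avail = [i for i in range(T) if t_star[i] > 0]
        if len(avail) < cap:
            return
        same_size = prev_row is not None and k > 0 and caps[k - 1] == cap
        for c in combinations(avail, cap):
            if same_size and c < prev_row:
                continue  # canonical order among interchangeable batches
            # prune: every remaining count must fit in the remaining batches
            ok = True
            for i in c:
                t_star[i] -= 1
            for i in range(T):
                if t_star[i] > remaining - 1:
                    ok = False
                    break
            if ok:
                N[k, list(c)] = 1
                yield from rec(k + 1, c)
                N[k, list(c)] = 0
            for i in c:
                t_star[i] += 1

    yield from rec(0, None)


def optimal_allocation(
    problem: AllocationProblem, max_space: int = DEFAULT_MAX_SPACE
) -> ScoredAllocation:
    """Brute-force D-optimal allocation (ties keep the first found).

    Raises
    ------
    BudgetExceededError
        If the search space exceeds ``max_space``.
    """
    best_score = -1
    best: np.ndarray | None = None
    for inc in enumerate_allocations(problem, max_space=max_space):
        score = d_criterion(inc)
        if score > best_score:
            best_score = score
            best = inc.copy()
    if best is None:
        raise BudgetExceededError("no feasible allocation enumerated")
    return ScoredAllocation(
        incidence=best,
        d_score=best_score,
        confounded=(best_score == 0),
        seed=None,
        algorithm="exhaustive",
    )


def all_subsets_incidence(n_treatments: int, batch_size: int) -> np.ndarray:
    """Incidence with one batch per ``batch_size``-subset of the treatments.

    With T treatments this gives ``C(T, k)`` batches in which every
    treatment appears ``C(T-1, k-1)`` times and every pair co-occurs
    ``C(T-2, k-2)`` times: a balanced incomplete-block design.  For five
    treatments in batches of three this is the known optimum of the
    30-subject benchmark cohort.
    """
    subsets = list(combinations(range(n_treatments), batch_size))
    N = np.zeros((len(subsets), n_treatments), dtype=int)
    for k, c in enumerate(subsets):
        N[k, list(c)] = 1
    return N
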