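"""Structured stochastic batch allocation (SBA).

After preallocation, the remainder is a binary allocation problem: every
treatment appears at most once per batch.  Batches are filled one at a
time; within a batch, treatments are chosen to keep the concurrence
matrix ``Lambda = N^T N`` — how often each pair of treatments has shared
a batch so far — as flat as possible:

1. *Forced* treatments, whose remaining count equals the number of
   remaining batches, must go in every remaining batch.
2. *Never-chosen* treatments (zero diagonal in Lambda) are added next,
   a uniformly random subset if they exceed the remaining capacity.
3. If the batch is still empty, a *seed pair* with the smallest
   off-diagonal concurrence starts it.
4. Remaining slots are filled one treatment at a time, each minimizing
   its summed concurrence with the treatments already in the batch.

All ties are broken uniformly at random from a single seeded stream —
the sole source of stochasticity — so one allocation is cheap and the
heuristic is meant to be run many times, keeping the best score.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import InfeasibleAllocationError
from .prealloc import preallocate
from .problem import AllocationProblem
from .scoring import ScoredAllocation, d_criterion

__all__ = [
    "AllocationState",
    "forced_treatments",
    "never_chosen_treatments",
    "seed_pair",
    "next_treatment",
    "allocate_batch",
    "sba_allocate",
]


@dataclass
class AllocationState:
    """Mutable mid-allocation record for the binary remainder problem.

    ``k`` is the 1-based index of the batch currently being filled.
    ``N`` holds the completed binary rows for batches ``1..k-1``;
    ``Lambda == N^T N`` over those rows.  ``t_star`` counts the subjects
    still to allocate per treatment, ``b_star`` the residual capacity of
    each batch.
    """

    N: np.ndarray
    Lambda: np.ndarray
    t_star: np.ndarray
    b_star: np.ndarray
    k: int
    rng: np.random.Generator

    @classmethod
    def initial(
        cls, t_star: np.ndarray, b_star: np.ndarray, rng: np.random.Generator
    ) -> "AllocationState":
        B, T = len(b_star), len(t_star)
        return cls(
            N=np.zeros((B, T), dtype=int),
            Lambda=np.zeros((T, T), dtype=int),
            t_star=np.asarray(t_star, dtype=int).copy(),
            b_star=np.asarray(b_star, dtype=int).copy(),
            k=1,
            rng=rng,
        )

    @property
    def n_batches(self) -> int:
        return self.N.shape[0]

    @property
    def remaining_batches(self) -> int:
        """Number of batches not yet completed, including the current one."""
        return self.n_batches - (self.k - 1)

    @property
    def available(self) -> list[int]:
        """Treatments with subjects left to allocate, in index order."""
        return [i for i in range(len(self.t_star)) if self.t_star[i] > 0]


def forced_treatments(state: AllocationState) -> set[int]:
    """Treatments that must appear in every remaining batch.

    These are the treatments whose remaining count equals the number of
    remaining batches; skipping any remaining batch would leave them
    unplaceable in the binary remainder.

    Raises
    ------
    InfeasibleAllocationError
        If more treatments are forced than the current batch can hold.
    """
    rem = state.remaining_batches
    forced = {i for i in state.available if state.t_star[i] == rem}
    cap = int(state.b_star[state.k - 1])
    if len(forced) > cap:
        raise InfeasibleAllocationError(
            f"batch {state.k}: {len(forced)} treatments are forced but "
            f"residual capacity is {cap}"
        )
    return forced


def never_chosen_treatments(state: AllocationState) -> set[int]:
    """Available treatments not yet placed in any batch of the remainder.

    Identified by a zero on the diagonal of the concurrence matrix.
    """
    return {i for i in state.available if state.Lambda[i, i] == 0}


def seed_pair(state: AllocationState, candidates: set[int]) -> tuple[int, int]:
    """Pick the pair of candidates with minimal off-diagonal concurrence.

    Starts an otherwise-empty batch.  Ties are broken uniformly at random.
    The diagonal of Lambda is a replication count, not a concurrence, so
    only off-diagonal entries compete.
    """
    cands = sorted(candidates)
    if len(cands) < 2:
        raise InfeasibleAllocationError(
            f"seed_pair needs at least 2 candidates, got {len(cands)}"
        )
    pairs = list(combinations(cands, 2))
    values = np.array([state.Lambda[i, j] for i, j in pairs])
    best = np.flatnonzero(values == values.min())
    return pairs[best[state.rng.integers(len(best))]]


def next_treatment(
    state: AllocationState, chosen: set[int], candidates: set[int]
) -> int:
    """Candidate minimizing summed concurrence with the chosen set.

    Returns the ``j`` in ``candidates`` with the smallest column sum of
    ``Lambda[chosen, j]``; ties are broken uniformly at random.
    """
    if not chosen or not candidates:
        raise InfeasibleAllocationError("next_treatment needs nonempty chosen and candidate sets")
    cands = sorted(candidates)
    rows = sorted(chosen)
    sums = state.Lambda[np.ix_(rows, cands)].sum(axis=0)
    best = np.flatnonzero(sums == sums.min())
    return cands[best[state.rng.integers(len(best))]]


def _lone_start(state: AllocationState, candidates: set[int]) -> int:
    """Single-slot fallback when a batch starts empty with capacity 1.

    A lone treatment creates no new concurrence, so the least-replicated
    candidate (smallest Lambda diagonal) is taken, ties at random.
    """
    cands = sorted(candidates)
    diag = np.array([state.Lambda[i, i] for i in cands])
    best = np.flatnonzero(diag == diag.min())
    return cands[best[state.rng.integers(len(best))]]


def allocate_batch(state: AllocationState) -> AllocationState:
    """Fill the current batch's row of N, update Lambda and t_star, advance k.

    Selection order: forced treatments, then never-chosen treatments
    (random subset on overflow), then a minimal-concurrence seed pair if
    the batch is still empty, then repeated minimal-column-sum picks.
    The incidence and concurrence matrices are updated once per batch,
    after the full set is chosen.

    Raises
    ------
    InfeasibleAllocationError
        If the forced set exceeds capacity, or fewer treatments remain
        available than the batch's residual capacity (a dead end: the
        completed allocation could not have row sums equal to b).
    """
    k = state.k
    cap = int(state.b_star[k - 1])
    rng = state.rng
    chosen: list[int] = []

    avail = state.available
    if len(avail) < cap:
        raise InfeasibleAllocationError(
            f"batch {k}: residual capacity {cap} but only {len(avail)} "
            f"treatments have subjects remaining"
        )

    for i in sorted(forced_treatments(state)):
        chosen.append(i)
    candidates = {i for i in avail if i not in chosen}

    room = cap - len(chosen)
    if room > 0:
        never = sorted(never_chosen_treatments(state) & candidates)
        if len(never) > room:
            never = list(rng.choice(never, size=room, replace=False))
        chosen.extend(int(i) for i in never)
        candidates.difference_update(chosen)

    if not chosen and cap >= 2 and len(candidates) >= 2:
        i, j = seed_pair(state, candidates)
        chosen.extend([i, j])
        candidates.difference_update((i, j))
    if not chosen and cap >= 1 and candidates:
        i = _lone_start(state, candidates)
        chosen.append(i)
        candidates.discard(i)

    while len(chosen) < cap and candidates:
        j = next_treatment(state, set(chosen), candidates)
        chosen.append(j)
        candidates.discard(j)

    idx = np.array(sorted(chosen), dtype=int)
    state.N[k - 1, idx] = 1
    state.Lambda[np.ix_(idx, idx)] += 1
    state.t_star[idx] -= 1
    state.k += 1
    return state


def sba_allocate(
    problem: AllocationProblem, seed: int | np.random.Generator
) -> ScoredAllocation:
    """Run one SBA pass: preallocate, fill every batch, score the result.

    Deterministic given ``(problem, seed)``.  The returned incidence is
    the preallocated quota plus the binary remainder; its column sums
    equal ``t`` and its row sums equal ``b``.
    """
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), int(seed)
    pre = preallocate(problem)
    state = AllocationState.initial(pre.t_star, pre.b_star, rng)
    for _ in range(problem.n_batches):
        allocate_batch(state)
    incidence = pre.N_star + state.N
    score = d_criterion(incidence)
    return ScoredAllocation(
        incidence=incidence,
        d_score=score,
        confounded=(score == 0),
        seed=seed_out,
        algorithm="sba",
    )
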