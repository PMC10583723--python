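"""Random binary allocation (RBA): the baseline comparator.

RBA shares SBA's preallocation and binary-remainder structure but picks
each batch's treatment set uniformly at random among the available
treatments, subject only to feasibility: treatments whose remaining
count equals the number of remaining batches are always included, since
they must appear in every remaining batch.  With that one constraint the
greedy pass almost never dead-ends on well-formed problems; if it does
(an unlucky early choice can strand capacity), the whole pass restarts
with fresh draws from the same stream, up to a bounded number of
attempts.
"""

from __future__ import annotations

import numpy as np

from .errors import InfeasibleAllocationError
from .prealloc import preallocate
from .problem import AllocationProblem
from .scoring import ScoredAllocation, d_criterion

__all__ = ["rba_allocate"]

_MAX_RESTARTS = 1000


def rba_allocate(
    problem: AllocationProblem, seed: int | np.random.Generator
) -> ScoredAllocation:
    """One random binary allocation of ``problem``; deterministic per seed.

    Raises
    ------
    InfeasibleAllocationError
        If no complete allocation is found within the restart budget.
    """
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), int(seed)
    pre = preallocate(problem)
    B = problem.n_batches
    T = problem.n_treatments

    for _ in range(_MAX_RESTARTS):
        t_star = pre.t_star.copy()
        N = np.zeros((B, T), dtype=int)
        dead_end = False
        for k in range(B):
            cap = int(pre.b_star[k])
            avail = np.flatnonzero(t_star > 0)
            remaining = B - k
            forced = [int(i) for i in avail if t_star[i] == remaining]
            if len(forced) > cap or len(avail) < cap:
                dead_end = True
                break
            rest = [int(i) for i in avail if t_star[i] < remaining]
            extra = cap - len(forced)
            chosen = list(forced)
            if extra > 0:
                chosen.extend(
                    int(i) for i in rng.choice(rest, size=extra, replace=False)
                )
            idx = np.array(chosen, dtype=int)
            N[k, idx] = 1
            t_star[idx] -= 1
        if not dead_end and (t_star == 0).all():
            incidence = pre.N_star + N
            score = d_criterion(incidence)
            return ScoredAllocation(
                incidence=incidence,
                d_score=score,
                confounded=(score == 0),
                seed=seed_out,
                algorithm="rba",
            )
    raise InfeasibleAllocationError(
        f"random binary allocation dead-ended {_MAX_RESTARTS} times; "
        "the problem is likely infeasible for a binary remainder"
    )
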