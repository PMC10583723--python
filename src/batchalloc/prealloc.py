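"""Preallocation: peel off the identical-per-batch part of the problem.

Each treatment's count splits as ``t = B*q + t_star`` with
``0 <= t_star_i < B``.  The quotient ``q_i`` subjects of treatment ``i``
go into every batch, leaving a *binary remainder* problem in which every
treatment appears at most once per batch.  Because the preallocated part
is identical across batches, it cannot distinguish one allocation of the
remainder from another, so the concurrence bookkeeping of the heuristic
starts from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleAllocationError
from .problem import AllocationProblem

__all__ = ["PreallocationResult", "preallocate"]


@dataclass(frozen=True)
class PreallocationResult:
    """Outcome of splitting a problem into quota and binary remainder.

    Attributes
    ----------
    q : per-treatment count placed in every batch (length T)
    t_star : per-treatment remainders, all < B (length T)
    b_star : residual batch capacities ``b_k - sum(q)`` (length B)
    N_star : B x T incidence of the preallocated part, every row equal to q
    """

    q: np.ndarray
    t_star: np.ndarray
    b_star: np.ndarray
    N_star: np.ndarray


def preallocate(problem: AllocationProblem) -> PreallocationResult:
    """Split ``problem`` into the per-batch quota and the binary remainder.

    Raises
    ------
    InfeasibleAllocationError
        If some batch is too small to hold the per-batch quota
        (``b_k < sum(q)``).
    """
    t = problem.t
    b = problem.b
    B = problem.n_batches
    q = t // B
    t_star = t - B * q
    b_star = b - int(q.sum())
    if (b_star < 0).any():
        bad = int(np.argmin(b_star))
        raise InfeasibleAllocationError(
            f"batch {bad + 1} (size {int(b[bad])}) cannot hold the "
            f"per-batch quota of {int(q.sum())} subjects"
        )
    N_star = np.tile(q, (B, 1))
    return PreallocationResult(q=q, t_star=t_star, b_star=b_star, N_star=N_star)
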