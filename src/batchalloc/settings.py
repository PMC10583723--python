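"""Registry of the four benchmark allocation settings.

The settings span the axes that matter for batch allocation: treatment
size imbalance, treatments per batch slot, and overall search-space
size.  None can be simplified by preallocation (every treatment count is
below the batch count).

=======  ==============================  =========  =======
Setting  treatment sizes                 max batch  batches
=======  ==============================  =========  =======
A        6, 6, 6, 6, 6                   3          10 x 3
B        10 x 10                         5          20 x 5
C        6, 7, 8, 8, 9                   3          12 x 3 + 1 x 2
D        5, 5, 8, 8, 10, 10, 12, 12,     5          20 x 5
         15, 15
=======  ==============================  =========  =======

Setting A's optimum is the balanced incomplete-block design with every
treatment triple as a batch; the other settings are too large to solve
exhaustively and are evaluated by comparing SBA against RBA.
"""

from __future__ import annotations

from .problem import AllocationProblem

__all__ = ["benchmark_settings", "SETTINGS"]

_SPECS: dict[str, tuple[list[int], int]] = {
    "A": ([6, 6, 6, 6, 6], 3),
    "B": ([10] * 10, 5),
    "C": ([6, 7, 8, 8, 9], 3),
    "D": ([5, 5, 8, 8, 10, 10, 12, 12, 15, 15], 5),
}


def benchmark_settings() -> dict[str, AllocationProblem]:
    """Build the four benchmark problems (labels "A".."D")."""
    out = {}
    for label, (sizes, max_batch) in _SPECS.items():
        counts = {f"T{i + 1}": n for i, n in enumerate(sizes)}
        out[label] = AllocationProblem.from_counts(counts, max_batch_size=max_batch)
    return out


SETTINGS = benchmark_settings()
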