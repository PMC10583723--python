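"""Allocation problems: a fixed cohort and a batch structure.

A problem couples per-treatment subject counts ``t`` (length ``T``) with
batch sizes ``b`` (length ``B``).  The cohort is fixed — treatments are
observed, not assigned — so the design question is purely which batch each
subject's sample is processed in.  The exact-fit requirement
``sum(t) == sum(b)`` is enforced: partially filled batches are rejected
rather than silently padded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ProblemValidationError

__all__ = ["AllocationProblem", "derive_batch_sizes", "validate_problem"]


def derive_batch_sizes(total_subjects: int, max_batch_size: int) -> list[int]:
    """Split ``total_subjects`` into near-equal batches of at most ``max_batch_size``.

    Uses the smallest feasible number of batches, ``B = ceil(total/max)``,
    with sizes differing by at most one and larger batches first.

    Examples
    --------
    >>> derive_batch_sizes(44, 8)
    [8, 8, 7, 7, 7, 7]
    >>> derive_batch_sizes(7, 3)
    [3, 2, 2]
    """
    total = int(total_subjects)
    cap = int(max_batch_size)
    if total < 1:
        raise ProblemValidationError(f"total_subjects must be >= 1, got {total}")
    if cap < 1:
        raise ProblemValidationError(f"max_batch_size must be >= 1, got {cap}")
    n_batches = -(-total // cap)  # ceil
    base, extra = divmod(total, n_batches)
    return [base + 1] * extra + [base] * (n_batches - extra)


@dataclass(frozen=True)
class AllocationProblem:
    """A fixed cohort to be allocated to processing batches.

    Parameters
    ----------
    treatment_labels
        Ordered, distinct treatment names.  All internal matrices use this
        column order.
    t
        Per-treatment subject counts, one per label.
    b
        Batch sizes.  ``sum(t)`` must equal ``sum(b)``.
    """

    treatment_labels: tuple[str, ...]
    t: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)

    def __init__(
        self,
        treatment_labels: Sequence[str],
        t: Sequence[int],
        b: Sequence[int],
    ) -> None:
        object.__setattr__(self, "treatment_labels", tuple(str(x) for x in treatment_labels))
        t_arr = np.asarray(t, dtype=int).copy()
        b_arr = np.asarray(b, dtype=int).copy()
        t_arr.setflags(write=False)
        b_arr.setflags(write=False)
        object.__setattr__(self, "t", t_arr)
        object.__setattr__(self, "b", b_arr)
        validate_problem(self)

    # -- derived quantities -------------------------------------------------

    @property
    def n_treatments(self) -> int:
        return len(self.treatment_labels)

    @property
    def n_batches(self) -> int:
        return len(self.b)

    @property
    def n_subjects(self) -> int:
        return int(self.t.sum())

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        *,
        batch_sizes: Sequence[int] | None = None,
        max_batch_size: int | None = None,
    ) -> "AllocationProblem":
        """Build a problem from ``{label: count}`` plus a batch structure.

        Exactly one of ``batch_sizes`` and ``max_batch_size`` must be given;
        with the latter, sizes are derived by :func:`derive_batch_sizes`.
        """
        if (batch_sizes is None) == (max_batch_size is None):
            raise ProblemValidationError(
                "give exactly one of batch_sizes or max_batch_size"
            )
        labels = list(counts)
        t = [int(counts[lab]) for lab in labels]
        if batch_sizes is None:
            batch_sizes = derive_batch_sizes(sum(t), int(max_batch_size))
        return cls(labels, t, batch_sizes)

    @classmethod
    def from_config(cls, config: Mapping) -> "AllocationProblem":
        """Build a problem from a parsed YAML/JSON config mapping.

        Expected shape::

            treatments: {label: count, ...}
            batch_sizes: [..]        # or
            max_batch_size: n
        """
        if "treatments" not in config:
            raise ProblemValidationError("config missing 'treatments' mapping")
        return cls.from_counts(
            config["treatments"],
            batch_sizes=config.get("batch_sizes"),
            max_batch_size=config.get("max_batch_size"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "AllocationProblem":
        """Read a problem config from a YAML or JSON file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_config(json.loads(text))
        return cls.from_config(yaml.safe_load(text))


def validate_problem(problem: AllocationProblem) -> AllocationProblem:
    """Check all structural invariants; return the problem unchanged.

    Raises
    ------
    ProblemValidationError
        On duplicate labels, nonpositive counts, fewer than two
        treatments, or ``sum(t) != sum(b)``.
    """
    labels = problem.treatment_labels
    t, b = problem.t, problem.b
    if len(set(labels)) != len(labels):
        raise ProblemValidationError(f"duplicate treatment labels in {labels!r}")
    if len(labels) != len(t):
        raise ProblemValidationError(
            f"{len(labels)} labels but {len(t)} treatment counts"
        )
    if len(labels) < 2:
        raise ProblemValidationError("need at least two treatments")
    if len(b) < 1:
        raise ProblemValidationError("need at least one batch")
    if (t < 1).any():
        raise ProblemValidationError(f"all treatment counts must be >= 1, got {t.tolist()}")
    if (b < 1).any():
        raise ProblemValidationError(f"all batch sizes must be >= 1, got {b.tolist()}")
    if int(t.sum()) != int(b.sum()):
        raise ProblemValidationError(
            f"cohort size {int(t.sum())} != total batch capacity {int(b.sum())}"
        )
    return problem
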