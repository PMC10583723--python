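"""D-criterion scoring of batch allocations.

An allocation is judged under the standard linear model

    y = intercept + treatment + batch + error,

with both categorical factors dummy-coded against a reference level
(drop-first).  The D-criterion is the determinant of the information
matrix ``X^T X``; maximizing it minimizes the generalized variance of the
parameter estimates.  A zero determinant means treatment and batch are
confounded and the model cannot be estimated.  Scores are only comparable
between allocations of the *same* problem.

Determinants are computed in exact integer arithmetic so that rankings
never suffer floating-point ties; see :mod:`batchalloc._det`.  The
information matrix is assembled directly from the incidence matrix
(``X^T X`` has a closed form in the incidence, batch sizes and treatment
counts), with the diagonal batch block ordered first so that Bareiss
elimination clears it cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._det import bareiss_determinant
from .errors import ConfoundedDesignError

__all__ = [
    "ScoredAllocation",
    "build_design_matrix",
    "d_criterion",
    "is_confounded",
    "contrast_variances",
]


@dataclass(frozen=True)
class ScoredAllocation:
    """A completed incidence matrix together with its D-criterion score.

    ``incidence`` is the full B x T matrix (preallocated quota plus binary
    remainder); ``d_score`` is the exact integer determinant of the
    information matrix; ``confounded`` is equivalent to ``d_score == 0``.
    ``algorithm``, ``seed`` and ``run_index`` record provenance.
    """

    incidence: np.ndarray
    d_score: int
    confounded: bool
    seed: int | None = None
    algorithm: str = ""
    run_index: int = 0

    def __post_init__(self) -> None:
        if self.confounded != (self.d_score == 0):
            raise ValueError("confounded flag inconsistent with d_score")
        if self.d_score < 0:
            raise ValueError("Gram determinant cannot be negative")


def build_design_matrix(incidence: np.ndarray) -> np.ndarray:
    """Expand an incidence matrix into the subjects x parameters 0/1 matrix.

    Columns are: intercept, treatment indicators 2..T, batch indicators
    2..B (first level of each factor is the reference).  Rows follow the
    canonical batch-major, treatment-minor order; the D-criterion is
    invariant to row order, so any other subject ordering scores the same.
    """
    N = np.asarray(incidence, dtype=int)
    B, T = N.shape
    p = 1 + (T - 1) + (B - 1)
    rows = []
    for k in range(B):
        for i in range(T):
            for _ in range(N[k, i]):
                row = np.zeros(p, dtype=int)
                row[0] = 1
                if i >= 1:
                    row[i] = 1
                if k >= 1:
                    row[T - 1 + k] = 1
                rows.append(row)
    return np.array(rows, dtype=int).reshape(len(rows), p)


def _information_matrix_batch_first(N: np.ndarray) -> list[list[int]]:
    """``X^T X`` with columns reordered: batch dummies first, then
    intercept and treatment dummies.  The symmetric permutation leaves the
    determinant unchanged and puts the diagonal batch block in the leading
    position, where fraction-free elimination clears it in O(B*T^2)."""
    B, T = N.shape
    t = N.sum(axis=0)
    b = N.sum(axis=1)
    n = int(t.sum())
    nb = B - 1
    size = nb + T  # (B-1) batch cols + intercept + (T-1) treatment cols
    G = [[0] * size for _ in range(size)]
    for k in range(1, B):
        G[k - 1][k - 1] = int(b[k])
        G[k - 1][nb] = G[nb][k - 1] = int(b[k])
        for j in range(1, T):
            G[k - 1][nb + j] = G[nb + j][k - 1] = int(N[k, j])
    G[nb][nb] = n
    for j in range(1, T):
        G[nb][nb + j] = G[nb + j][nb] = int(t[j])
        G[nb + j][nb + j] = int(t[j])
    return G


def d_criterion(incidence: np.ndarray) -> int:
    """Exact D-criterion score: ``det(X^T X)`` as a Python integer.

    Zero signals confounding.  Larger is better within one problem;
    scores from different problems are not comparable.
    """
    N = np.asarray(incidence, dtype=int)
    if N.ndim != 2:
        raise ValueError("incidence must be a 2-D matrix")
    det = bareiss_determinant(_information_matrix_batch_first(N))
    # det(X^T X) is a Gram determinant, hence >= 0
    assert det >= 0
    return det


def is_confounded(incidence: np.ndarray) -> bool:
    """True iff the information matrix is singular (D-criterion zero)."""
    return d_criterion(incidence) == 0


def contrast_variances(incidence: np.ndarray) -> dict[tuple[int, int], float]:
    """Variance of each simple treatment contrast, error variance set to 1.

    For every unordered treatment pair ``(i, j)`` (0-based indices), the
    variance of the estimated difference between treatments ``i`` and
    ``j`` under the intercept + treatment + batch model, read from the
    inverse information matrix.  Only relative comparisons between
    allocations of the same problem are meaningful.

    Raises
    ------
    ConfoundedDesignError
        If the allocation is confounded (singular information matrix).
    """
    N = np.asarray(incidence, dtype=int)
    B, T = N.shape
    X = build_design_matrix(N)
    info = (X.T @ X).astype(float)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConfoundedDesignError("information matrix is singular") from exc
    # guard against inv "succeeding" on a numerically singular matrix
    if d_criterion(N) == 0:
        raise ConfoundedDesignError("information matrix is singular")
    # treatment effect coordinates: reference level 0 has coefficient 0,
    # level i >= 1 sits in column i of X
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(T), 2):
        if i == 0:
            var = cov[j, j]
        else:
            var = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
        out[(i, j)] = float(var)
    return out
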