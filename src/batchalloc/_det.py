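"""Exact integer determinants via fraction-free (Bareiss) elimination.

All D-criterion scores are integers, and allocation rankings must compare
them exactly — two candidate designs can differ by a few parts in 1e9 —
so floating-point determinants are never used on the scoring path.
Bareiss elimination keeps every intermediate value an integer, and Python
integers are arbitrary precision, so the result is bit-exact.
"""

from __future__ import annotations

from typing import Sequence

__all__ = ["bareiss_determinant"]


def bareiss_determinant(matrix: Sequence[Sequence[int]]) -> int:
    """Exact determinant of a square integer matrix.

    The input is copied; rows are pivoted when a diagonal entry vanishes.
    Returns a Python ``int`` (0 for singular matrices).
    """
    m = [[int(x) for x in row] for row in matrix]
    n = len(m)
    if any(len(row) != n for row in m):
        raise ValueError("matrix must be square")
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for i in range(n - 1):
        if m[i][i] == 0:
            for r in range(i + 1, n):
                if m[r][i] != 0:
                    m[i], m[r] = m[r], m[i]
                    sign = -sign
                    break
            else:
                return 0
        piv = m[i][i]
        row_i = m[i]
        for r in range(i + 1, n):
            row_r = m[r]
            mri = row_r[i]
            for c in range(i + 1, n):
                # Bareiss update: division is exact by construction
                row_r[c] = (row_r[c] * piv - mri * row_i[c]) // prev
        prev = piv
    return sign * m[n - 1][n - 1]
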