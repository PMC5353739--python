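"""Global alignment percent identity between gliadin proteins.

Needleman-Wunsch with match +1, mismatch 0 and a linear gap penalty of -0.9
per gapped column (stored internally as integers x10, so the DP is exact).
With these scores every co-optimal alignment has the same number of identical
columns and the same number of gaps, which makes percent identity well-defined
regardless of traceback tie-breaking (an integer identity difference would
have to equal 0.9x an integer gap difference).

Identity = identical columns / aligned columns after trimming terminal-gap
columns, x100. The pair is canonically ordered before alignment so the
statistic is exactly symmetric.
"""
from __future__ import annotations

import numpy as np

from .errors import InputError
from .records import ProteinRecord

_MATCH = 10
_GAP = 9  # i.e. -0.9 on the x10 integer scale


def _nw_matrix(a: str, b: str) -> np.ndarray:
    n, m = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    jj = np.arange(m + 1, dtype=np.int64)
    H[0] = -_GAP * jj
    A = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        s = np.where(bb == aa[i - 1], _MATCH, 0)
        M = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] - _GAP)
        A[0] = -_GAP * i
        A[1:] = M + _GAP * jj[1:]
        np.maximum.accumulate(A, out=A)
        H[i] = A - _GAP * jj
    return H


def _traceback(a: str, b: str, H: np.ndarray) -> list[tuple[str | None, str | None]]:
    """Canonical traceback, preferring diagonal, then up, then left."""
    i, j = len(a), len(b)
    cols: list[tuple[str | None, str | None]] = []
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and H[i, j] == H[i - 1, j - 1] + (_MATCH if a[i - 1] == b[j - 1] else 0)
        ):
            cols.append((a[i - 1], b[j - 1]))
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] - _GAP:
            cols.append((a[i - 1], None))
            i -= 1
        else:
            cols.append((None, b[j - 1]))
            j -= 1
    cols.reverse()
    return cols


def align_columns(a: str, b: str) -> list[tuple[str | None, str | None]]:
    """Aligned columns of the canonical optimal global alignment."""
    return _traceback(a, b, _nw_matrix(a, b))


def alignment_score(a: str, b: str) -> float:
    """Optimal global alignment score (match +1, mismatch 0, gap -0.9)."""
    return float(_nw_matrix(a, b)[len(a), len(b)]) / 10.0


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Percent identity (0-100) between two protein sequences."""
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise InputError("pairwise_identity requires non-empty sequences")
    if sa == sb:
        return 100.0
    if sb < sa:  # canonical order => exact symmetry
        sa, sb = sb, sa
    cols = align_columns(sa, sb)
    lo = 0
    hi = len(cols)
    while lo < hi and (cols[lo][0] is None or cols[lo][1] is None):
        lo += 1
    while hi > lo and (cols[hi - 1][0] is None or cols[hi - 1][1] is None):
        hi -= 1
    trimmed = cols[lo:hi]
    if not trimmed:
        return 0.0
    identical = sum(1 for x, y in trimmed if x is not None and x == y)
    return 100.0 * identical / len(trimmed)
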