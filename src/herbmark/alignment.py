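"""Global pairwise alignment and percent identity.

Needleman-Wunsch with match +1, mismatch -1, gap -2, end gaps penalized.
Identity is matches / alignment columns of the optimal alignment; ties among
equal-score traceback moves prefer diagonal, then up, then left.  Because
tie alignments under this scoring can carry different match counts, the pair
is canonicalized (shorter-then-lexicographically-smaller sequence first)
before aligning, which makes :func:`global_identity` symmetric by
construction.

Short pairs (max length <= 128 nt) always use the full dynamic program; long
pairs use a banded DP whose band starts at 2x the length difference + 16 and
doubles until the score stabilizes, falling back to the full matrix.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2

_FULL_DP_MAX = 128
_NEG = -(10**9)


@njit(cache=True)
def _nw_kernel(a, b, band):  # pragma: no cover - exercised via wrapper
    """Banded NW; band >= max(n, m) means full DP.

    Returns (score, matches, columns, aligned_both)."""
    n = a.size
    m = b.size
    S = np.full((n + 1, m + 1), _NEG, np.int64)
    P = np.zeros((n + 1, m + 1), np.uint8)  # 1 diag, 2 up, 3 left
    # band on the diagonal offset c = j - i
    c_lo = min(0, m - n) - band
    c_hi = max(0, m - n) + band
    S[0, 0] = 0
    for i in range(1, n + 1):
        if -i >= c_lo:
            S[i, 0] = GAP * i
            P[i, 0] = 2
    for j in range(1, m + 1):
        if j <= c_hi:
            S[0, j] = GAP * j
            P[0, j] = 3
    for i in range(1, n + 1):
        j_start = max(1, i + c_lo)
        j_end = min(m, i + c_hi)
        for j in range(j_start, j_end + 1):
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            best = S[i - 1, j - 1] + sub
            ptr = 1
            up = S[i - 1, j] + GAP
            if up > best:
                best = up
                ptr = 2
            left = S[i, j - 1] + GAP
            if left > best:
                best = left
                ptr = 3
            S[i, j] = best
            P[i, j] = ptr
    score = S[n, m]
    # traceback
    i = n
    j = m
    matches = 0
    columns = 0
    aligned_both = 0
    while i > 0 or j > 0:
        ptr = P[i, j]
        columns += 1
        if ptr == 1:
            if a[i - 1] == b[j - 1]:
                matches += 1
            aligned_both += 1
            i -= 1
            j -= 1
        elif ptr == 2:
            i -= 1
        else:
            j -= 1
    return score, matches, columns, aligned_both


class AlignmentStats(NamedTuple):
    identity: float
    query_coverage: float
    score: int
    matches: int
    columns: int


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return arr.copy()


def _align(a: str, b: str) -> tuple[int, int, int, int]:
    ea, eb = _encode(a), _encode(b)
    n, m = ea.size, eb.size
    full_band = max(n, m)
    if full_band <= _FULL_DP_MAX:
        return _nw_kernel(ea, eb, full_band)
    band = 2 * abs(n - m) + 16
    prev = None
    while True:
        res = _nw_kernel(ea, eb, min(band, full_band))
        if band >= full_band or (prev is not None and res[0] == prev[0]):
            return res
        prev = res
        band *= 2


def align_stats(query: str, reference: str) -> AlignmentStats:
    """Align *query* to *reference* globally.

    ``identity`` is symmetric (pair canonicalized before aligning);
    ``query_coverage`` is the fraction of query bases aligned to reference
    bases (end gaps in the reference reduce it).
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    a, b = query, reference
    if (len(b), b) < (len(a), a):
        a, b = b, a
    score, matches, columns, aligned_both = _align(a, b)
    return AlignmentStats(
        identity=matches / columns,
        query_coverage=aligned_both / len(query),
        score=int(score),
        matches=int(matches),
        columns=int(columns),
    )


def global_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the optimal global alignment.

    Symmetric; 1.0 iff the sequences are equal; in [0, 1].
    """
    if a == b:
        return 1.0
    return align_stats(a, b).identity
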