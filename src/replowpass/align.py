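"""Smith-Waterman local alignment primitives (numba-accelerated).

Scoring follows the package-wide overlap convention: match +1, mismatch -1,
gap -2 (linear).  Identity is defined as matches / alignment columns, where
columns count every aligned pair and every gapped position once.

Tie-breaking is fully deterministic so that accelerated and exhaustive code
paths produce identical results:

* the best cell is the first maximum in row-major scan order;
* traceback prefers diagonal over up over left at equal scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np

MATCH = 1
MISMATCH = -1
GAP = -2


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment between two coded sequences."""

    score: int
    matches: int
    columns: int
    a_start: int
    a_end: int  # half-open on sequence a
    b_start: int
    b_end: int  # half-open on sequence b

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@numba.njit(cache=True)
def _sw_score(a, b, match, mismatch, gap):  # pragma: no cover - numba
    m = len(b)
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.zeros(m + 1, dtype=np.int32)
    best = 0
    for i in range(1, len(a) + 1):
        ai = a[i - 1]
        cur[0] = 0
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = prev[j - 1] + s
            u = prev[j] + gap
            if u > h:
                h = u
            l = cur[j - 1] + gap
            if l > h:
                h = l
            if h < 0:
                h = 0
            cur[j] = h
            if h > best:
                best = h
        prev, cur = cur, prev
    return best


@numba.njit(cache=True)
def _sw_full(a, b, match, mismatch, gap):  # pragma: no cover - numba
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            u = H[i - 1, j] + gap
            if u > h:
                h = u
                p = 2
            l = H[i, j - 1] + gap
            if l > h:
                h = l
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            P[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    matches = 0
    columns = 0
    i, j = bi, bj
    while i > 0 and j > 0 and P[i, j] != 0:
        p = P[i, j]
        columns += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return best, matches, columns, i, bi, j, bj


def sw_score(a: np.ndarray, b: np.ndarray) -> int:
    """Best local alignment score only (cheap screen)."""
    return int(_sw_score(a, b, MATCH, MISMATCH, GAP))


def sw_align(a: np.ndarray, b: np.ndarray) -> LocalAlignment:
    """Best local alignment with identity statistics and spans."""
    score, matches, columns, a0, a1, b0, b1 = _sw_full(a, b, MATCH, MISMATCH, GAP)
    return LocalAlignment(int(score), int(matches), int(columns),
                          int(a0), int(a1), int(b0), int(b1))


def min_overlap_score(shorter_len: int, min_identity: float, min_coverage: float) -> int:
    """Score lower bound implied by the identity/coverage thresholds.

    Any alignment with identity >= t and columns >= c0 * Lmin has score
    >= (3t - 2) * c0 * Lmin under +1/-1/-2 scoring (valid for t > 2/3);
    pairs scoring below this bound cannot form an overlap edge.
    """
    if min_identity <= 2 / 3:
        return 0
    return math.floor((3 * min_identity - 2) * min_coverage * shorter_len)


def safe_seed_length(min_len: int, min_identity: float, min_coverage: float,
                     max_len: int | None = None, cap: int = 13) -> int:
    """Longest k such that any qualifying overlap must contain an exact k-mer.

    An alignment with c columns and identity >= t has at most floor((1-t)c)
    non-match events splitting the matched columns into runs; the longest run
    is at least ceil((c - e) / (e + 1)).  Minimised over the admissible column
    range this gives a seed length that provably loses no edges.
    """
    cmin = math.ceil(min_coverage * min_len)
    cmax = max_len if max_len is not None else 4 * min_len
    best = cap
    for c in range(max(cmin, 1), max(cmax, cmin) + 1):
        e = math.floor((1 - min_identity) * c)
        run = math.ceil((c - e) / (e + 1))
        if run < best:
            best = run
    return max(1, best)


def warm_up() -> None:
    """Trigger numba compilation on a trivial input (optional)."""
    a = np.array([0, 1, 2, 3], dtype=np.uint8)
    sw_score(a, a)
    sw_align(a, a)
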