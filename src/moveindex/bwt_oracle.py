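"""Brute-force BWT ground truth: suffix array, BWT, LCP, LF, naive matching.

Everything here is the reference the move structure is checked against.
The suffix array is built by prefix doubling over integer character ranks
(the custom collation ``$ < # < A < C < G < T`` is applied by mapping
characters to ranks first), the LCP array by Kasai's algorithm, and the
LF-mapping is materialized as a full length-n array so ``lf_direct`` is a
single lookup.  None of this is run-length compressed — that is the point:
it is the O(n) ground truth, valid at test scale.
"""

from __future__ import annotations

import dataclasses
from functools import cached_property

import numpy as np

from .sequence_io import ALPHABET, RANK, SequenceText, TERMINATOR


def _text_string(text: SequenceText | str) -> str:
    return text.text if isinstance(text, SequenceText) else text


def _suffix_array(ranks: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array over integer ranks, O(n log^2 n)."""
    n = len(ranks)
    rank = ranks.astype(np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        if k < n:
            second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        r_ord = rank[order]
        s_ord = second[order]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r_ord[1:] != r_ord[:-1]) | (s_ord[1:] != s_ord[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _kasai_lcp(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    n = len(sa)
    inv = np.empty(n, dtype=np.int64)
    inv[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = inv[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


@dataclasses.dataclass
class BwtOracle:
    """Suffix array, BWT, LF and (lazily) LCP for a terminated text."""

    text: str
    sa: np.ndarray
    bwt: str
    lf: np.ndarray
    char_counts: dict[str, int]

    @cached_property
    def lcp(self) -> np.ndarray:
        codes = np.array([RANK[c] for c in self.text], dtype=np.int64)
        return _kasai_lcp(codes, self.sa)

    @property
    def n(self) -> int:
        return len(self.text)


def build_oracle(text: SequenceText | str) -> BwtOracle:
    """Build the full suffix-array/BWT/LF ground truth for ``text``.

    Equivalent to sorting all rotations of the text lexicographically
    (the unique smallest terminator makes suffix order and rotation order
    coincide) and reading off the last column.
    """
    s = _text_string(text)
    if not s or s[-1] != TERMINATOR or s.count(TERMINATOR) != 1:
        raise ValueError("text must contain exactly one terminator, at the end")
    codes = np.array([RANK[c] for c in s], dtype=np.int64)
    n = len(s)
    sa = _suffix_array(codes)
    bwt_codes = codes[(sa - 1) % n]
    bwt = "".join(ALPHABET[c] for c in bwt_codes)

    char_counts: dict[str, int] = {}
    below = 0
    for c in ALPHABET:
        count = int(np.count_nonzero(codes == RANK[c]))
        if count:
            char_counts[c] = below
            below += count

    lf = np.empty(n, dtype=np.int64)
    for c, start in char_counts.items():
        idx = np.flatnonzero(bwt_codes == RANK[c])
        lf[idx] = start + np.arange(len(idx))
    return BwtOracle(text=s, sa=sa, bwt=bwt, lf=lf, char_counts=char_counts)


def lf_direct(oracle: BwtOracle, j: int) -> int:
    """LF-mapping at BWT offset ``j``: C[bwt[j]] + rank(bwt[j], j)."""
    if not 0 <= j < oracle.n:
        raise IndexError(f"BWT offset {j} out of range [0, {oracle.n})")
    return int(oracle.lf[j])


def invert_bwt(oracle: BwtOracle) -> str:
    """Recover the text by chaining LF n times from the terminator's row.

    Row 0 of the BWM starts with the terminator; following LF spells the
    text right-to-left.
    """
    n = oracle.n
    out = []
    j = 0
    for _ in range(n):
        out.append(oracle.bwt[j])
        j = int(oracle.lf[j])
    rev = "".join(reversed(out))  # terminator first, then T[0..n-2]
    return rev[1:] + rev[0]


def count_naive(text: SequenceText | str, pattern: str) -> int:
    """Number of (possibly overlapping) occurrences of ``pattern``."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    s = _text_string(text)
    count = 0
    pos = s.find(pattern)
    while pos != -1:
        count += 1
        pos = s.find(pattern, pos + 1)
    return count


def matching_statistics_naive(text: SequenceText | str, pattern: str) -> list[int]:
    """MS[i]: length of the longest prefix of pattern[i:] occurring in text."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    s = _text_string(text)
    m = len(pattern)
    out = []
    for i in range(m):
        length = 0
        while i + length < m and pattern[i : i + length + 1] in s:
            length += 1
        out.append(length)
    return out
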