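"""Repositioning thresholds from LCP minima.

When a query character ``a`` mismatches the character of the BWT run the
cursor sits in, the cursor must reposition to the nearest ``a`` above
(``j_up``, the last offset of the closest a-run above) or below (``j_dn``,
the first offset of the closest a-run below).  The right choice is the one
whose rotation shares the longer common prefix with the cursor's rotation.

Because the LCP between two BWM rows is the minimum of the LCP array over
the offsets between them, the boundary is the position of the minimum LCP
value between consecutive occurrences of ``a``: offsets above that minimum
are closer (in prefix terms) to the occurrence above, offsets at or below
it to the occurrence below.  One threshold per (run, character) — clamped
into the run — encodes the whole decision.  Ties (equal LCP minima) are
broken by taking the leftmost minimum, i.e. repositioning goes upward only
when its common prefix is strictly longer.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .bwt_oracle import BwtOracle
from .move_index import RunEntry
from .sequence_io import BASES


def compute_thresholds(
    oracle: BwtOracle, runs: Sequence[RunEntry]
) -> list[dict[str, int]]:
    """One threshold per (run, non-run character), aligned with ``runs``.

    For run ``i`` spanning ``[p, p+len)`` and character ``a`` occurring
    both above (last at ``u``) and below (first at ``v``): the threshold is
    the leftmost position of the minimum of ``lcp[u+1 .. v]``, clamped into
    ``[p, p+len]``.  With no ``a`` above it is ``p`` (always reposition
    down); with none below, ``p+len`` (always up); characters absent from
    the whole BWT get ``p`` and are rejected earlier by the query layer.
    """
    lcp = np.asarray(oracle.lcp)
    bwt_bytes = np.frombuffer(oracle.bwt.encode("ascii"), dtype=np.uint8)

    occ: dict[str, np.ndarray] = {}
    gap_argmin: dict[str, np.ndarray] = {}
    for a in BASES:
        positions = np.flatnonzero(bwt_bytes == ord(a))
        occ[a] = positions
        if len(positions) >= 2:
            mins = np.empty(len(positions) - 1, dtype=np.int64)
            for g in range(len(positions) - 1):
                u, v = int(positions[g]), int(positions[g + 1])
                # leftmost argmin over lcp[u+1 .. v]
                mins[g] = u + 1 + int(np.argmin(lcp[u + 1 : v + 1]))
            gap_argmin[a] = mins
        else:
            gap_argmin[a] = np.empty(0, dtype=np.int64)

    out: list[dict[str, int]] = []
    for run in runs:
        thresholds: dict[str, int] = {}
        lo, hi = run.p, run.p + run.len
        for a in BASES:
            if a == run.c:
                continue
            positions = occ[a]
            idx = int(np.searchsorted(positions, run.p))
            has_above = idx > 0
            has_below = idx < len(positions)
            if not has_above:
                thresholds[a] = lo
            elif not has_below:
                thresholds[a] = hi
            else:
                t = int(gap_argmin[a][idx - 1])
                thresholds[a] = min(max(t, lo), hi)
        out.append(thresholds)
    return out


def brute_force_choice(oracle: BwtOracle, j: int, a: str) -> str | None:
    """Reference up/down decision by direct longest-common-prefix comparison.

    Compares the rotation at BWT row ``j`` with the nearest ``a``-carrying
    rows above and below, choosing ``"up"`` only when the upper candidate's
    common prefix is strictly longer.  Returns None when ``a`` does not
    occur in the BWT.  Independent of the threshold representation; used to
    verify it.
    """
    positions = np.flatnonzero(
        np.frombuffer(oracle.bwt.encode("ascii"), dtype=np.uint8) == ord(a)
    )
    if len(positions) == 0:
        return None
    idx = int(np.searchsorted(positions, j))
    up = int(positions[idx - 1]) if idx > 0 else None
    dn = int(positions[idx]) if idx < len(positions) else None
    if up is None:
        return "dn"
    if dn is None:
        return "up"
    return "up" if _suffix_lcp(oracle, j, up) > _suffix_lcp(oracle, j, dn) else "dn"


def _suffix_lcp(oracle: BwtOracle, row_a: int, row_b: int) -> int:
    sa, text = oracle.sa, oracle.text
    x, y = int(sa[row_a]), int(sa[row_b])
    length = 0
    n = len(text)
    while x + length < n and y + length < n and text[x + length] == text[y + length]:
        length += 1
    return length


def threshold_choice(thresholds: dict[str, int], a: str, j: int) -> str:
    """Decision encoded by a stored per-run threshold: up below it, down at
    or above it."""
    return "up" if j < thresholds[a] else "dn"
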