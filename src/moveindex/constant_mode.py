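"""Constant mode: run splitting for bounded fast-forwards, plus per-row
repositioning pointers.

Splitting (after Nishimoto & Tabei) subdivides BWT runs until no run's
LF-image interval contains 2d or more run heads; a fast-forward scan can
then cross fewer than 2d run boundaries, so every LF-mapping query does a
constant-bounded amount of work.  The repositioning pointers make the
mismatch step constant-time as well: each row stores, for every other
character of the DNA alphabet, the nearest run above and below carrying
that character — six pointers per row for DNA.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left
from typing import Optional, Sequence

from .bwt_oracle import BwtOracle
from .move_index import MoveTable, RunEntry
from .sequence_io import BASES


@dataclasses.dataclass(frozen=True)
class SplitConfig:
    """Splitting parameter d >= 2: after splitting, every LF query performs
    strictly fewer than 2d fast-forward steps."""

    d: int = 5

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("splitting parameter d must be >= 2")


def split_runs(
    oracle: BwtOracle, runs: Sequence[RunEntry], cfg: SplitConfig
) -> list[RunEntry]:
    """Split runs until every run's LF image holds fewer than 2d run heads.

    Iterates to a fixpoint: while some run's LF-image interval
    ``[LF(p), LF(p)+len)`` contains >= 2d heads of the current run set,
    that run is cut at the preimage of the d-th such head.  Each output
    run is a sub-interval of exactly one input run; the cut points are
    flagged so downstream consumers can tell split boundaries from
    character changes.
    """
    d = cfg.d
    lf = oracle.lf
    current = list(runs)
    while True:
        heads = [r.p for r in current]
        out: list[RunEntry] = []
        changed = False
        for run in current:
            image_start = int(lf[run.p])
            lo = bisect_left(heads, image_start)
            hi = bisect_left(heads, image_start + run.len)
            if hi - lo >= 2 * d:
                # cut at the preimage of the d-th head inside the image
                cut = run.p + (heads[lo + d - 1] - image_start)
                out.append(RunEntry(run.c, cut - run.p, run.p, run.split))
                out.append(RunEntry(run.c, run.p + run.len - cut, cut, True))
                changed = True
            else:
                out.append(run)
        current = out
        if not changed:
            return current


def attach_reposition_pointers(table: MoveTable) -> MoveTable:
    """Populate up_run/dn_run on every row by one backward + forward sweep.

    ``up_run[a]`` is the greatest run index above with character ``a``,
    ``dn_run[a]`` the least below, or None where no such run exists.
    Pointers are stored for every base other than the row's own character.
    """
    rows = table.rows
    last_seen: dict[str, Optional[int]] = {a: None for a in BASES}
    for i, row in enumerate(rows):
        row.up_run = {a: last_seen[a] for a in BASES if a != row.c}
        if row.c in last_seen:
            last_seen[row.c] = i
    next_seen: dict[str, Optional[int]] = {a: None for a in BASES}
    for i in range(len(rows) - 1, -1, -1):
        row = rows[i]
        row.dn_run = {a: next_seen[a] for a in BASES if a != row.c}
        if row.c in next_seen:
            next_seen[row.c] = i
    return table
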