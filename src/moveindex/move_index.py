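"""The move structure: a run-table index over the BWT supporting LF-mapping
by row arithmetic plus bounded forward scans ("fast-forwards").

One table row per BWT run stores the run character ``c``, length, head
offset ``p``, the LF-mapping of the head ``pi`` and the index ``xi`` of the
run containing ``pi``.  An LF query at offset ``j`` inside run ``i`` is then

    LF[j] = rows[i].pi + (j - rows[i].p)

followed by a forward scan from ``rows[i].xi`` to the run actually holding
the result.  No rank/select bitvectors or wavelet trees are involved —
only row arithmetic and sequential scanning, which is what makes the
structure cache-friendly.

Both ``p`` and ``pi`` are kept as explicit absolute offsets.  Collapsing
them into one relative offset would shrink rows, but absolute offsets keep
the arithmetic transparent and are required by the count query, which
reports interval widths in global BWT coordinates.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .bwt_oracle import BwtOracle
from .sequence_io import ALPHABET

FORMAT_TAG = "moveindex-v1"


class IndexFormatError(ValueError):
    """Raised when a serialized index cannot be loaded."""


@dataclasses.dataclass(frozen=True)
class RunEntry:
    """One BWT run: character, length, head offset.  ``split`` marks a run
    head introduced by constant-mode splitting (same character as the
    preceding run)."""

    c: str
    len: int
    p: int
    split: bool = False


@dataclasses.dataclass
class MoveRow:
    c: str
    len: int
    p: int
    pi: int
    xi: int
    split: bool = False
    #: per mismatch character: BWT offset in [p, p+len]; offsets below it
    #: reposition upward, at or above it downward (thresholds module).
    thresholds: Optional[dict[str, int]] = None
    #: constant mode only: nearest run above/below carrying each character.
    up_run: Optional[dict[str, Optional[int]]] = None
    dn_run: Optional[dict[str, Optional[int]]] = None


@dataclasses.dataclass(frozen=True)
class BiPointer:
    """A BWT position carried as (containing run index, global offset)."""

    run: int
    off: int


@dataclasses.dataclass
class Counters:
    """Instrumentation of the query work: LF calls, fast-forward scan steps
    and repositioning scan steps, with running maxima per call."""

    lf_calls: int = 0
    fast_forward_steps: int = 0
    max_fast_forwards: int = 0
    repositions: int = 0
    reposition_scan_steps: int = 0
    max_reposition_scans: int = 0

    def reset(self) -> None:
        for field in dataclasses.fields(self):
            setattr(self, field.name, 0)


@dataclasses.dataclass
class MoveTable:
    rows: list[MoveRow]
    n: int
    r_original: int
    char_counts: dict[str, int]
    mode: str = "default"
    d: Optional[int] = None
    instrument: bool = True
    counters: Counters = dataclasses.field(default_factory=Counters)

    def __post_init__(self) -> None:
        self._heads = np.array([row.p for row in self.rows], dtype=np.int64)

    @property
    def r(self) -> int:
        return len(self.rows)

    def char_total(self, c: str) -> int:
        """Number of occurrences of ``c`` in the text."""
        if c not in self.char_counts:
            return 0
        larger = [ALPHABET[i] for i in range(ALPHABET.index(c) + 1, len(ALPHABET))]
        for nxt in larger:
            if nxt in self.char_counts:
                return self.char_counts[nxt] - self.char_counts[c]
        return self.n - self.char_counts[c]


def build_rlbwt(bwt: str) -> list[RunEntry]:
    """Run-length encode the BWT into maximal same-character runs."""
    if not bwt:
        raise ValueError("BWT must be non-empty")
    runs = []
    pos = 0
    for c, group in itertools.groupby(bwt):
        length = sum(1 for _ in group)
        runs.append(RunEntry(c=c, len=length, p=pos))
        pos += length
    return runs


def _run_of(heads: np.ndarray, j: int) -> int:
    return int(np.searchsorted(heads, j, side="right")) - 1


def build_move_table(
    oracle: BwtOracle,
    runs: Optional[Sequence[RunEntry]] = None,
    mode: str = "default",
    d: Optional[int] = None,
) -> MoveTable:
    """Assemble the move table from the oracle's BWT.

    In ``constant`` mode the runs are first split so every LF query needs
    fewer than ``2d`` fast-forwards, and per-row repositioning pointers are
    attached; in both modes per-row thresholds are computed for the
    mismatch (repositioning) logic.
    """
    from .constant_mode import SplitConfig, attach_reposition_pointers, split_runs
    from .thresholds import compute_thresholds

    if mode not in ("default", "constant"):
        raise ValueError(f"unknown mode {mode!r}")
    if runs is None:
        runs = build_rlbwt(oracle.bwt)
    r_original = len(runs)
    _check_runs(oracle, runs)
    if mode == "constant":
        if d is None:
            d = 5
        runs = split_runs(oracle, runs, SplitConfig(d=d))
    else:
        d = None

    heads = np.array([r.p for r in runs], dtype=np.int64)
    threshold_sets = compute_thresholds(oracle, runs)
    rows = []
    for entry, thr in zip(runs, threshold_sets):
        pi = int(oracle.lf[entry.p])
        xi = _run_of(heads, pi)
        rows.append(
            MoveRow(
                c=entry.c, len=entry.len, p=entry.p, pi=pi, xi=xi,
                split=entry.split, thresholds=thr,
            )
        )
    table = MoveTable(
        rows=rows,
        n=oracle.n,
        r_original=r_original,
        char_counts=dict(oracle.char_counts),
        mode=mode,
        d=d,
    )
    if mode == "constant":
        attach_reposition_pointers(table)
    return table


def _check_runs(oracle: BwtOracle, runs: Sequence[RunEntry]) -> None:
    pos = 0
    for entry in runs:
        if entry.p != pos or entry.len < 1:
            raise ValueError("runs must tile [0, n) contiguously")
        if oracle.bwt[entry.p : entry.p + entry.len] != entry.c * entry.len:
            raise ValueError(f"run at {entry.p} disagrees with the BWT")
        pos += entry.len
    if pos != oracle.n:
        raise ValueError("runs do not cover the BWT")


def run_of_offset(table: MoveTable, j: int) -> int:
    """Binary-search the run containing global BWT offset ``j``."""
    if not 0 <= j < table.n:
        raise IndexError(f"BWT offset {j} out of range [0, {table.n})")
    return _run_of(table._heads, j)


def fast_forward(table: MoveTable, i: int, j_target: int) -> tuple[int, int]:
    """Scan forward from run ``i`` to the run containing ``j_target``.

    Returns ``(run index, scan steps taken)``.  The start row must lie at
    or before the target.
    """
    if j_target >= table.n:
        raise IndexError(f"target offset {j_target} out of range")
    rows = table.rows
    if rows[i].p > j_target:
        raise ValueError("fast_forward start row lies beyond the target")
    steps = 0
    while i + 1 < len(rows) and rows[i + 1].p <= j_target:
        i += 1
        steps += 1
    return i, steps


def move_lf(table: MoveTable, ptr: BiPointer) -> BiPointer:
    """One LF-mapping step: row arithmetic plus fast-forward."""
    row = table.rows[ptr.run]
    if not row.p <= ptr.off < row.p + row.len:
        raise ValueError(f"pointer {ptr} not inside its run")
    off2 = row.pi + (ptr.off - row.p)
    run2, steps = fast_forward(table, row.xi, off2)
    if table.instrument:
        c = table.counters
        c.lf_calls += 1
        c.fast_forward_steps += steps
        if steps > c.max_fast_forwards:
            c.max_fast_forwards = steps
    return BiPointer(run=run2, off=off2)


# ---------------------------------------------------------------------------
# Serialization: versioned, deterministic JSON.
# ---------------------------------------------------------------------------

def serialize(table: MoveTable, path: str | Path) -> None:
    payload = {
        "format": FORMAT_TAG,
        "n": table.n,
        "r_original": table.r_original,
        "mode": table.mode,
        "d": table.d,
        "char_counts": table.char_counts,
        "rows": [
            [
                row.c, row.len, row.p, row.pi, row.xi, int(row.split),
                row.thresholds, row.up_run, row.dn_run,
            ]
            for row in table.rows
        ],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, separators=(",", ":")))


def deserialize(path: str | Path) -> MoveTable:
    raw = Path(path).read_text()
    try:
        payload = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise IndexFormatError(f"{path}: truncated or corrupt index ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("format") != FORMAT_TAG:
        raise IndexFormatError(
            f"{path}: unsupported index format {payload.get('format')!r}"
            if isinstance(payload, dict)
            else f"{path}: not a moveindex file"
        )
    rows = [
        MoveRow(
            c=c, len=length, p=p, pi=pi, xi=xi, split=bool(split),
            thresholds=thr, up_run=up, dn_run=dn,
        )
        for c, length, p, pi, xi, split, thr, up, dn in payload["rows"]
    ]
    return MoveTable(
        rows=rows,
        n=payload["n"],
        r_original=payload["r_original"],
        char_counts=payload["char_counts"],
        mode=payload["mode"],
        d=payload["d"],
    )


def table_stats(table: MoveTable) -> dict:
    """Summary statistics reported by the ``stats`` command."""
    return {
        "n": table.n,
        "r_original": table.r_original,
        "rows": table.r,
        "n_over_r": table.n / table.r_original,
        "split_growth": table.r / table.r_original,
        "mode": table.mode,
        "d": table.d,
    }
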