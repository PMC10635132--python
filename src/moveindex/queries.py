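"""Query layer: pseudo matching lengths, backward-search counting, and the
interleaved multi-read driver.

A pseudo matching length (PML) is a one-pass, lower approximation of a
matching statistic: walking the read right to left, each position where the
cursor's BWT character equals the read character extends the current match
by one; each mismatch repositions the cursor to the nearest matching run
(direction decided by the run's threshold) and resets the length to zero.

The count query is classic backward search, except that interval updates
reuse the repositioning machinery: the top pointer always moves downward to
the first matching offset, the bottom pointer upward to the last one.

``process_batch`` interleaves many reads in one thread, round-robin, with
the LF step split into two phases: compute the destination offset and issue
a prefetch hint, then complete the fast-forward on the next visit.  The
hint is a no-op hook here; the control flow is the latency-hiding loop
shape, and results are bit-identical to sequential processing.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Optional

from .move_index import BiPointer, MoveTable, fast_forward, move_lf, run_of_offset
from .sequence_io import BASES
from .thresholds import threshold_choice


class CharacterAbsentError(KeyError):
    """The query character never occurs in the indexed text."""


@dataclasses.dataclass(frozen=True)
class PmlVector:
    """Per-position pseudo matching lengths of one read, left-to-right."""

    name: str
    lengths: tuple[int, ...]


@dataclasses.dataclass(frozen=True)
class SearchRange:
    top: Optional[BiPointer]
    bottom: Optional[BiPointer]
    empty: bool = False

    @property
    def width(self) -> int:
        if self.empty:
            return 0
        return self.bottom.off - self.top.off + 1


def prefetch_hint(table: MoveTable, run_index: int) -> None:
    """Hook invoked before each LF destination access; no-op placeholder
    for a memory prefetch on platforms that support one."""


# ---------------------------------------------------------------------------
# Repositioning
# ---------------------------------------------------------------------------

def reposition(table: MoveTable, ptr: BiPointer, a: str) -> BiPointer:
    """Move a mismatching cursor to the nearest BWT offset holding ``a``.

    The row's threshold decides the direction: offsets below it go up to
    the last offset of the nearest a-run above, the rest go down to the
    first offset of the nearest a-run below.  Default mode finds the target
    run by scanning run-to-run (scan steps instrumented); constant mode
    follows the stored pointer in one step.  Both return the same target.
    """
    row = table.rows[ptr.run]
    if row.c == a:
        raise ValueError("reposition called without a mismatch")
    if table.char_total(a) == 0:
        raise CharacterAbsentError(a)
    direction = threshold_choice(row.thresholds, a, ptr.off)
    if table.mode == "constant" and row.up_run is not None:
        target = row.up_run[a] if direction == "up" else row.dn_run[a]
        if target is None:  # thresholds guarantee the direction exists
            raise CharacterAbsentError(a)
        scan_steps = 0
    else:
        target = ptr.run
        scan_steps = 0
        step = -1 if direction == "up" else 1
        while True:
            target += step
            scan_steps += 1
            if target < 0 or target >= len(table.rows):
                raise CharacterAbsentError(a)
            if table.rows[target].c == a:
                break
    if table.instrument:
        c = table.counters
        c.repositions += 1
        c.reposition_scan_steps += scan_steps
        if scan_steps > c.max_reposition_scans:
            c.max_reposition_scans = scan_steps
    trow = table.rows[target]
    off = trow.p + trow.len - 1 if direction == "up" else trow.p
    return BiPointer(run=target, off=off)


# ---------------------------------------------------------------------------
# PML computation (single-read state; also drives the batch scheduler)
# ---------------------------------------------------------------------------

class _PmlState:
    """Right-to-left PML walk over one read, one position per step, with
    the LF completed lazily so a prefetch hint can precede it."""

    __slots__ = ("name", "seq", "k", "ptr", "length", "out", "pending", "done")

    def __init__(self, name: str, seq: str):
        if not seq:
            raise ValueError("empty read")
        self.name = name
        self.seq = seq
        self.k = len(seq) - 1
        self.ptr = BiPointer(run=0, off=0)  # fixed start: BWT offset 0
        self.length = 0
        self.out = [0] * len(seq)
        self.pending: Optional[tuple[int, int]] = None
        self.done = False

    def step(self, table: MoveTable, prefetch: Callable[[MoveTable, int], None]) -> None:
        if self.pending is not None:
            xi, off2 = self.pending
            self.pending = None
            run2, steps = fast_forward(table, xi, off2)
            if table.instrument:
                c = table.counters
                c.lf_calls += 1
                c.fast_forward_steps += steps
                if steps > c.max_fast_forwards:
                    c.max_fast_forwards = steps
            self.ptr = BiPointer(run=run2, off=off2)
        if self.k < 0:
            self.done = True
            return
        ch = self.seq[self.k]
        row = table.rows[self.ptr.run]
        if ch == row.c:
            self.length += 1
        elif ch not in BASES or table.char_total(ch) == 0:
            # character missing from the index ('N' or absent base):
            # reset, hold position, skip the LF for this step
            self.length = 0
            self.out[self.k] = 0
            self.k -= 1
            return
        else:
            self.ptr = reposition(table, self.ptr, ch)
            self.length = 0
        self.out[self.k] = self.length
        row = table.rows[self.ptr.run]
        off2 = row.pi + (self.ptr.off - row.p)
        prefetch(table, row.xi)
        self.pending = (row.xi, off2)
        self.k -= 1

    def result(self) -> PmlVector:
        return PmlVector(name=self.name, lengths=tuple(self.out))


def compute_pml(table: MoveTable, read: str, name: str = "") -> PmlVector:
    """Pseudo matching lengths of one read (left-to-right order)."""
    state = _PmlState(name, read)
    while not state.done:
        state.step(table, prefetch_hint)
    return state.result()


# ---------------------------------------------------------------------------
# Backward search
# ---------------------------------------------------------------------------

def initial_range(table: MoveTable, a: str) -> SearchRange:
    """BWM rows prefixed by the single character ``a`` (from C counts)."""
    if a not in BASES:
        raise ValueError(f"not a base: {a!r}")
    total = table.char_total(a)
    if total == 0:
        return SearchRange(top=None, bottom=None, empty=True)
    top_off = table.char_counts[a]
    bottom_off = top_off + total - 1
    return SearchRange(
        top=BiPointer(run=run_of_offset(table, top_off), off=top_off),
        bottom=BiPointer(run=run_of_offset(table, bottom_off), off=bottom_off),
    )


class _CountState:
    """Backward search over one pattern, one character per step."""

    __slots__ = ("name", "pattern", "pos", "range", "pending", "done", "count")

    def __init__(self, name: str, pattern: str):
        if not pattern:
            raise ValueError("empty pattern")
        if any(ch not in BASES for ch in pattern):
            raise ValueError(f"pattern {name!r} contains non-base characters")
        self.name = name
        self.pattern = pattern
        self.pos = len(pattern) - 1
        self.range: Optional[SearchRange] = None
        self.pending: Optional[tuple[tuple[int, int], tuple[int, int]]] = None
        self.done = False
        self.count = 0

    def _finish(self, count: int) -> None:
        self.count = count
        self.done = True

    def step(self, table: MoveTable, prefetch: Callable[[MoveTable, int], None]) -> None:
        if self.pending is not None:
            (txi, toff), (bxi, boff) = self.pending
            self.pending = None
            trun, tsteps = fast_forward(table, txi, toff)
            brun, bsteps = fast_forward(table, bxi, boff)
            if table.instrument:
                c = table.counters
                c.lf_calls += 2
                c.fast_forward_steps += tsteps + bsteps
                c.max_fast_forwards = max(c.max_fast_forwards, tsteps, bsteps)
            self.range = SearchRange(
                top=BiPointer(trun, toff), bottom=BiPointer(brun, boff)
            )
        if self.pos < 0:
            self._finish(self.range.width)
            return
        ch = self.pattern[self.pos]
        self.pos -= 1
        if self.range is None:
            self.range = initial_range(table, ch)
            if self.range.empty:
                self._finish(0)
            return
        top = _seek_down(table, self.range.top, ch)
        bottom = _seek_up(table, self.range.bottom, ch)
        if top is None or bottom is None or top.off > bottom.off:
            self._finish(0)
            return
        self.range = SearchRange(top=top, bottom=bottom)
        # queue both LF steps behind a prefetch hint
        trow = table.rows[self.range.top.run]
        brow = table.rows[self.range.bottom.run]
        toff = trow.pi + (self.range.top.off - trow.p)
        boff = brow.pi + (self.range.bottom.off - brow.p)
        prefetch(table, trow.xi)
        prefetch(table, brow.xi)
        self.pending = ((trow.xi, toff), (brow.xi, boff))

    def result(self) -> tuple[str, int]:
        return (self.name, self.count)


def _seek_down(table: MoveTable, ptr: BiPointer, a: str) -> Optional[BiPointer]:
    """First offset >= ptr.off whose run character is ``a`` (top pointer:
    the j_dn flavour of repositioning)."""
    row = table.rows[ptr.run]
    if row.c == a:
        return ptr
    if table.mode == "constant" and row.dn_run is not None and a in row.dn_run:
        target = row.dn_run[a]
    else:
        target = _scan_for(table, ptr.run, a, step=1)
    if target is None:
        return None
    return BiPointer(run=target, off=table.rows[target].p)


def _seek_up(table: MoveTable, ptr: BiPointer, a: str) -> Optional[BiPointer]:
    """Last offset <= ptr.off whose run character is ``a`` (bottom pointer:
    the j_up flavour)."""
    row = table.rows[ptr.run]
    if row.c == a:
        return ptr
    if table.mode == "constant" and row.up_run is not None and a in row.up_run:
        target = row.up_run[a]
    else:
        target = _scan_for(table, ptr.run, a, step=-1)
    if target is None:
        return None
    trow = table.rows[target]
    return BiPointer(run=target, off=trow.p + trow.len - 1)


def _scan_for(table: MoveTable, run: int, a: str, step: int) -> Optional[int]:
    scan_steps = 0
    while True:
        run += step
        scan_steps += 1
        if run < 0 or run >= len(table.rows):
            if table.instrument:
                table.counters.reposition_scan_steps += scan_steps
            return None
        if table.rows[run].c == a:
            if table.instrument:
                c = table.counters
                c.repositions += 1
                c.reposition_scan_steps += scan_steps
                if scan_steps > c.max_reposition_scans:
                    c.max_reposition_scans = scan_steps
            return run


def backward_search_count(table: MoveTable, pattern: str, name: str = "") -> int:
    """Number of text occurrences of ``pattern`` via backward search."""
    state = _CountState(name, pattern)
    while not state.done:
        state.step(table, prefetch_hint)
    return state.count


# ---------------------------------------------------------------------------
# Interleaved multi-read driver
# ---------------------------------------------------------------------------

def process_batch(
    table: MoveTable,
    reads: Iterable[tuple[str, str]],
    query: str = "pml",
    batch_size: int = 16,
    prefetch: Callable[[MoveTable, int], None] = prefetch_hint,
):
    """Process reads round-robin, up to ``batch_size`` concurrently.

    Each active read advances by one inner-loop iteration per visit, with a
    prefetch hint issued before each LF destination access; a finished
    read's slot immediately loads the next read.  Results come back in
    input order and are identical to sequential processing.  The default of
    16 concurrent reads matches the point where prefetch gains plateau.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if query == "pml":
        make_state = _PmlState
    elif query == "count":
        make_state = _CountState
    else:
        raise ValueError(f"unknown query {query!r}")

    read_list = list(reads)
    results: list = [None] * len(read_list)
    next_read = 0
    slots: list[tuple[int, object]] = []  # (read index, state)
    while next_read < len(read_list) and len(slots) < batch_size:
        name, seq = read_list[next_read]
        slots.append((next_read, make_state(name, seq)))
        next_read += 1

    cursor = 0
    while slots:
        idx, state = slots[cursor]
        state.step(table, prefetch)
        if state.done:
            results[idx] = state.result()
            if next_read < len(read_list):
                name, seq = read_list[next_read]
                slots[cursor] = (next_read, make_state(name, seq))
                next_read += 1
                cursor = (cursor + 1) % len(slots)
            else:
                slots.pop(cursor)
                if slots:
                    cursor %= len(slots)
        else:
            cursor = (cursor + 1) % len(slots)
    return results


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_pml(results: Iterable[PmlVector], path) -> None:
    """">name" line followed by space-separated lengths, per read."""
    with open(path, "w") as fh:
        for vec in results:
            fh.write(f">{vec.name}\n")
            fh.write(" ".join(str(v) for v in vec.lengths) + "\n")


def write_counts(results: Iterable[tuple[str, int]], path) -> None:
    """TSV: read name, occurrence count."""
    with open(path, "w") as fh:
        for name, count in results:
            fh.write(f"{name}\t{count}\n")
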