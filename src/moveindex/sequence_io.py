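"""Sequence input/output and synthetic pangenome generation.

The index operates on a single concatenated text over the six-character
ordered alphabet ``$ < # < A < C < G < T``: ``$`` is the unique terminator
appended at the very end, and ``#`` separates consecutive documents so that
no match can span a document boundary.  All offsets are 0-based and all
intervals half-open.

Besides FASTA/FASTQ round-tripping this module provides a self-contained
synthetic-pangenome generator: a random base haplotype plus mutated copies
(i.i.d. substitutions, geometric-length indels), and a read simulator with
substitution errors and uniform-random decoy reads.  Everything is
reproducible from an integer seed, so tests and benchmarks never need a
download.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TERMINATOR = "$"
SEPARATOR = "#"
#: Collation order of the text alphabet, smallest first.
ALPHABET = "$#ACGT"
BASES = "ACGT"
RANK = {c: i for i, c in enumerate(ALPHABET)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class FastaError(ValueError):
    """Raised for malformed or empty FASTA/FASTQ input."""


def char_less(a: str, b: str) -> bool:
    """True if character ``a`` collates strictly before ``b``."""
    return RANK[a] < RANK[b]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class SequenceText:
    """The concatenated, separator-joined, terminated text to be indexed.

    ``doc_boundaries`` holds ``(name, start, end)`` per document with
    half-open ``[start, end)`` coordinates into ``text``.
    """

    text: str
    doc_boundaries: tuple[tuple[str, int, int], ...]
    includes_revcomp: bool = False

    @property
    def n(self) -> int:
        return len(self.text)

    @property
    def n_documents(self) -> int:
        return len(self.doc_boundaries)

    def document(self, idx: int) -> str:
        name, start, end = self.doc_boundaries[idx]
        return self.text[start:end]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if not self.text or self.text[-1] != TERMINATOR:
            raise ValueError("text must end with the terminator")
        if self.text.count(TERMINATOR) != 1:
            raise ValueError("terminator must occur exactly once")
        expected_seps = len(self.doc_boundaries) - 1
        if self.text.count(SEPARATOR) != expected_seps:
            raise ValueError("separator count must be #docs - 1")
        pos = 0
        for i, (name, start, end) in enumerate(self.doc_boundaries):
            if start != pos or end <= start:
                raise ValueError(f"document {name!r} has bad boundaries")
            doc = self.text[start:end]
            if any(ch not in BASES for ch in doc):
                raise ValueError(f"document {name!r} contains special characters")
            pos = end + 1  # skip separator (or terminator for the last doc)
        if pos != len(self.text):
            raise ValueError("boundaries do not tile the text")


@dataclasses.dataclass(frozen=True)
class ReadSet:
    """Query reads: unique names, non-empty sequences over {A,C,G,T,N}."""

    reads: tuple[tuple[str, str], ...]
    source_format: str = "fasta"

    def __post_init__(self) -> None:
        names = [name for name, _ in self.reads]
        if len(set(names)) != len(names):
            raise ValueError("read names must be unique")
        if any(not seq for _, seq in self.reads):
            raise ValueError("read sequences must be non-empty")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclasses.dataclass(frozen=True)
class PangenomeSpec:
    """Parameters of the synthetic pangenome.

    Defaults describe a small intra-species collection: 10 haplotypes
    derived from a 50 kb base sequence, with one substitution per kilobase
    and a tenth as many indels (geometric lengths, mean 3 bp).
    """

    base_length: int = 50_000
    n_haplotypes: int = 10
    substitution_rate: float = 1e-3
    indel_rate: float = 1e-4
    mean_indel_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_length < 1:
            raise ValueError("base_length must be >= 1")
        if self.n_haplotypes < 1:
            raise ValueError("n_haplotypes must be >= 1")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mean_indel_len < 1.0:
            raise ValueError("mean_indel_len must be >= 1")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``[(name, uppercased sequence), ...]``.

    Multi-line records are allowed; record order is preserved.  Raises
    :class:`FastaError` naming the offending line for empty input or input
    that does not start with a header.
    """
    path = Path(path)
    _check_leadin(path, ">")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTQ; qualities are ignored."""
    path = Path(path)
    _check_leadin(path, "@")
    try:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
    except ValueError as exc:
        raise FastaError(f"{path}: malformed FASTQ ({exc})") from exc
    if not records:
        raise FastaError(f"{path}: no FASTQ records found")
    return records


def _check_leadin(path: Path, marker: str) -> None:
    try:
        text_lines = path.read_text().splitlines()
    except FileNotFoundError:
        raise
    for lineno, line in enumerate(text_lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(marker):
            raise FastaError(
                f"{path}: line {lineno}: expected a {marker!r} header, got {line[:30]!r}"
            )
        return
    raise FastaError(f"{path}: empty file")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def load_reads(path: str | Path) -> ReadSet:
    """Load reads from FASTA or FASTQ, sniffing the format from the header."""
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            raise FastaError(f"{path}: empty file")
    if first == ">":
        return ReadSet(tuple(read_fasta(path)), source_format="fasta")
    if first == "@":
        return ReadSet(tuple(read_fastq(path)), source_format="fastq")
    raise FastaError(f"{path}: unrecognized read format (expected FASTA or FASTQ)")


# ---------------------------------------------------------------------------
# Text assembly
# ---------------------------------------------------------------------------

def build_text(
    records: Sequence[tuple[str, str]],
    include_revcomp: bool = False,
    ambiguity_policy: str = "map_to_A",
) -> SequenceText:
    """Concatenate records into a separator-joined, terminated text.

    With ``include_revcomp`` the reverse complement of every record is
    appended as an extra document after all the originals.  Non-ACGT letters
    are handled per ``ambiguity_policy``: ``map_to_A`` rewrites them to
    ``A`` (keeps coordinates stable), ``strip`` deletes them.
    """
    if not records:
        raise ValueError("at least one record is required")
    if ambiguity_policy not in ("map_to_A", "strip"):
        raise ValueError(f"unknown ambiguity_policy {ambiguity_policy!r}")

    docs: list[tuple[str, str]] = []
    for name, seq in records:
        seq = seq.upper()
        if ambiguity_policy == "map_to_A":
            cleaned = "".join(ch if ch in BASES else "A" for ch in seq)
        else:
            cleaned = "".join(ch for ch in seq if ch in BASES)
        if not cleaned:
            raise ValueError(f"record {name!r} is empty after ambiguity handling")
        docs.append((name, cleaned))
    if include_revcomp:
        docs.extend((f"{name}_rc", reverse_complement(seq)) for name, seq in list(docs))

    parts: list[str] = []
    boundaries: list[tuple[str, int, int]] = []
    pos = 0
    for i, (name, seq) in enumerate(docs):
        if i:
            parts.append(SEPARATOR)
            pos += 1
        boundaries.append((name, pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    parts.append(TERMINATOR)
    text = SequenceText("".join(parts), tuple(boundaries), include_revcomp)
    text.validate()
    return text


# ---------------------------------------------------------------------------
# Synthetic pangenome
# ---------------------------------------------------------------------------

def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def _mutate(
    base: np.ndarray,
    rng: np.random.Generator,
    sub_rate: float,
    indel_rate: float,
    mean_indel_len: float,
) -> np.ndarray:
    length = len(base)
    codes = base.copy()
    if sub_rate > 0:
        mask = rng.random(length) < sub_rate
        n_sub = int(mask.sum())
        if n_sub:
            # shift by 1..3 mod 4 guarantees the base actually changes
            codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_sub)) % 4
    if indel_rate > 0:
        positions = np.flatnonzero(rng.random(length) < indel_rate)
        if len(positions):
            segments: list[np.ndarray] = []
            prev = 0
            for pos in positions:
                if pos < prev:  # swallowed by an earlier deletion
                    continue
                segments.append(codes[prev:pos])
                indel_len = int(rng.geometric(1.0 / mean_indel_len))
                if rng.random() < 0.5:
                    prev = min(length, pos + indel_len)  # deletion
                else:
                    segments.append(rng.integers(0, 4, size=indel_len))  # insertion
                    prev = pos
            segments.append(codes[prev:])
            codes = np.concatenate(segments)
    return codes


def generate_pangenome(spec: PangenomeSpec) -> list[tuple[str, str]]:
    """Simulate haplotypes: a random base sequence plus mutated copies.

    Haplotype 0 is uniform-random over ACGT; each later haplotype is an
    independently mutated copy of haplotype 0.  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.integers(0, 4, size=spec.base_length)
    records = [("hap0", _codes_to_str(base))]
    for k in range(1, spec.n_haplotypes):
        mutated = _mutate(
            base, rng, spec.substitution_rate, spec.indel_rate, spec.mean_indel_len
        )
        records.append((f"hap{k}", _codes_to_str(mutated)))
    return records


def generate_reads(
    text: SequenceText,
    n_reads: int,
    read_len: int,
    error_rate: float = 0.0,
    decoy_fraction: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Sample reads from the documents of ``text`` plus random decoys.

    Genuine reads are uniform over all valid (document, start) positions —
    they never span a separator — with i.i.d. substitution errors at
    ``error_rate``.  Each read is a decoy (uniform-random sequence) with
    probability ``decoy_fraction``.
    """
    doc_lens = [end - start for _, start, end in text.doc_boundaries]
    if read_len > max(doc_lens):
        raise ValueError(
            f"read_len {read_len} exceeds the longest document ({max(doc_lens)})"
        )
    starts_per_doc = np.array([max(0, dl - read_len + 1) for dl in doc_lens])
    cum = np.cumsum(starts_per_doc)
    total_positions = int(cum[-1])

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        if rng.random() < decoy_fraction:
            seq = _codes_to_str(rng.integers(0, 4, size=read_len))
            reads.append((f"decoy{i}", seq))
            continue
        flat = int(rng.integers(total_positions))
        doc_idx = int(np.searchsorted(cum, flat, side="right"))
        offset = flat - (int(cum[doc_idx - 1]) if doc_idx else 0)
        _, doc_start, _ = text.doc_boundaries[doc_idx]
        seq = text.text[doc_start + offset : doc_start + offset + read_len]
        if error_rate > 0:
            codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            lookup = np.zeros(256, dtype=np.int64)
            for b, ch in enumerate(BASES):
                lookup[ord(ch)] = b
            codes4 = lookup[codes]
            mask = rng.random(read_len) < error_rate
            n_err = int(mask.sum())
            if n_err:
                codes4[mask] = (codes4[mask] + rng.integers(1, 4, size=n_err)) % 4
            seq = _codes_to_str(codes4)
        reads.append((f"read{i}", seq))
    return ReadSet(tuple(reads), source_format="fasta")
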