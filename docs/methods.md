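# Methods

## Text model and alphabet

The index operates on a single string over the ordered six-character
alphabet `$ < # < A < C < G < T`. Input FASTA records are concatenated in
order, joined by the separator `#` and terminated by a single `$` at the
very end. The separator guarantees that no pattern over `{A,C,G,T}` can
match across a document boundary, and — because queries never contain
specials — a query cursor that lands in a `#` or `$` run always takes the
mismatch path there. All offsets are 0-based and all intervals half-open;
any 1-based convention in external descriptions of these structures is
converted at the documentation boundary only.

Non-ACGT letters are handled at text-assembly time by a policy:
`map_to_A` (default; deterministic and length-preserving) or `strip`.
Optionally the reverse complement of every record is appended as an extra
document, doubling the document count; the flag is off by default.

## Ground truth (bwt_oracle)

The oracle is the package's independent reference: suffix array by numpy
prefix doubling (O(n log² n); the unique terminator guarantees strictly
sorted suffixes, making rotation order and suffix order coincide), BWT by
`bwt[i] = text[(sa[i]−1) mod n]`, LCP by Kasai's algorithm (computed
lazily — only threshold construction needs it), and the LF-mapping
materialized as a full array `LF[j] = C[bwt[j]] + rank(bwt[j], j)`. Naive
counting and naive matching statistics use direct string search. Every
move-structure query is tested against these, exhaustively at small n.

Prefix doubling was chosen over an induced-sorting implementation because
build times at the scales used here (n up to ~5·10⁵) are fractions of a
second; no external-memory or parsing-based construction is attempted.

## The move table (move_index)

One row per BWT run with explicit `(c, ℓ, p, π, ξ)`. An LF step computes
`off′ = π + (off − p)` and fast-forwards from row `ξ` by linear scan until
the row containing `off′` is reached. Both `p` and `π` are stored as
absolute offsets; collapsing them into a single relative offset is a known
space optimization that this package deliberately rejects — absolute
offsets keep the row arithmetic transparent and the count query needs
global BWT coordinates for interval widths.

Instrumentation (LF calls, fast-forward steps with per-call maximum,
repositioning scans with per-call maximum) is first-class and toggleable
via `MoveTable.instrument`; the counts are the index's predictability
story, and the exhaustive tests switch them off in hot loops.

Serialization is a single versioned JSON document with sorted keys, so
rebuilding the same input byte-identically reproduces the index file.
JSON was chosen over a binary container to keep the artifact text-only and
platform-stable; the format check and truncation handling raise explicit
errors rather than corrupting silently.

## Constant mode (constant_mode)

Run splitting follows the Nishimoto–Tabei scheme, implemented as iteration
to a fixpoint: while some run's LF-image interval `[LF(p), LF(p)+ℓ)`
contains ≥ 2d run heads of the current run set, that run is cut at the
preimage of the d-th such head. At the fixpoint every LF image holds fewer
than 2d heads, so a fast-forward crosses strictly fewer than 2d run
boundaries — the property the tests verify exhaustively for d ∈ {2, 3, 5}.
Splitting operates on the run list and triggers a full table rebuild
rather than patching `π`/`ξ` in place; desk-scale builds are cheap and the
rebuild keeps the construction single-pathed. Split boundaries are flagged
on the run entries so the "consecutive runs differ in character" invariant
remains checkable. The default `d = 5` keeps splitting very mild (growth
factors ~1.00x on the synthetic collections) while still exercising the
machinery; it is configurable on the command line. No attempt is made to
reproduce any particular reference split set — the guaranteed contract is
the 2d bound, which is representation-independent.

Repositioning pointers are populated by one backward and one forward sweep:
for each row and each base other than the row's character, the nearest run
above and below carrying that base (or None). For DNA rows that is six
pointers per row; rows of special characters carry eight so that a cursor
sitting in a separator run can still reposition to any base.

## Thresholds

For run `i` and mismatch character `a` occurring last at `u` above the run
and first at `v` below it, the threshold is the leftmost position of the
minimum of `lcp[u+1 .. v]`, clamped into `[p, p+ℓ]`: offsets above the
minimum share a longer prefix with the occurrence above, offsets at or
below it with the occurrence below. Boundary cases: no `a` above → `p`
(always down); none below → `p+ℓ` (always up). The LCP-array positions
between consecutive occurrences of each base are precomputed once per
character (O(σn) total), then clamped per run.

Tie-breaking is fixed rather than arbitrary: taking the *leftmost* LCP
minimum is equivalent to repositioning upward only when the upper
candidate's common prefix is *strictly* longer. The brute-force oracle in
the tests uses exactly that strict rule, making the comparison
well-defined; the clamped per-run representation is verified against it at
every (run, character, in-run offset) on small texts, which is
representation-independent.

## Queries

**PML.** The cursor starts at BWT offset 0 (a fixed, documented choice —
any start offset yields a valid PML vector, but a fixed one makes
cross-implementation comparison reproducible) and scans the read right to
left. Match: length +1, record, LF. Mismatch: reposition (threshold
decides up/down; default mode scans run-to-run, constant mode follows the
stored pointer — both land on the same offset), reset length to 0, record,
LF. A character absent from the index entirely (including `N`, which is
treated as a guaranteed mismatch rather than rewritten, preserving read
coordinates) records 0, holds the cursor in place and skips the LF — the
minimal-state-change rule for a case the structure does not define.
Consequences tested: PML ≤ naive matching statistic everywhere, every
positive PML names a true occurrence, and `PML[k] ≤ PML[k+1] + 1`.

**Count.** Backward search maintains a top and bottom pointer; updating
them reuses the repositioning machinery with the direction forced — top
moves down to the first matching offset, bottom up to the last — skipping
the move when the pointer's run already matches; crossing pointers or a
missing target yield 0, otherwise both pointers take an LF step and the
final width `bottom − top + 1` is the occurrence count. Equivalence with
naive counting is exhaustive over all short substrings of a test text plus
random (mostly absent) patterns, in both modes.

**Interleaved driver.** `process_batch` keeps up to `batch_size` read
states (default 16, where prefetch gains plateau) and advances them
round-robin by one inner-loop iteration each. The LF step is split into
two phases: compute the destination offset and issue a prefetch hint for
the destination row, then complete the fast-forward on the slot's next
visit. The hint is a no-op hook — this package implements the loop shape,
not hardware prefetching — and results are bit-identical to sequential
processing for any batch size, which the tests assert for 1, 2, 16 and 32.

## Synthetic data

The generator emulates an intra-species haplotype collection: haplotype 0
uniform-random over ACGT; each further haplotype an independent copy with
i.i.d. substitutions (default 10⁻³ per base), indels at 10⁻⁴ per base with
geometric lengths of mean 3, derived reproducibly from one integer seed.
Reads are substrings sampled uniformly over all valid (document, start)
positions — never spanning separators — with i.i.d. substitution errors,
and each read is, with probability `decoy_fraction`, replaced by a
uniform-random decoy.

What this does and does not show: the synthetic collections reproduce the
*repetitiveness* that makes `r ≪ n` (the run-count ratio test shows ten
haplotypes costing < 2× the runs of one), but not the long structural
variants, mobile elements, sequencing-error profiles or base-composition
biases of real pangenomes and nanopore reads. Passing tests therefore
establish correctness of the index and queries, and the qualitative
scaling behaviour — not performance claims on real hardware or data, which
are out of scope here (no cache-miss measurements, no wall-clock
comparisons, no real prefetch instructions).

## Problem sizes

The verification suite uses 100 random 1 kb texts plus ten ~50 kb
synthetic pangenomes for the exhaustive LF checks, 1 kb texts for the
splitting bound, ≤ 300-base texts for the exhaustive threshold
comparison, 1000 simulated 150 bp reads for PML identity and batch
invariance (soundness against naive matching statistics on a 200–300 read
subset, where the naive oracle dominates the cost), a 500-base text for
the count-query sweep, and a 10 × 50 kb pangenome for run-count scaling.
These sizes make every "exhaustive" claim literally exhaustive at desk
scale while the whole suite stays fast.

## Known limitations

- Construction is in-memory and quadratic-log at worst; this is a
  correctness-first implementation, not a big-data builder (no
  parsing-based BWT construction, no external memory).
- The index file is verbose JSON; no compressed or memory-mapped layout.
- PMLs only: no two-pass matching-statistics/MEM computation, and no
  classification layer on top of the PML vectors.
- Single-end reads; gzip inputs are not transparently decompressed.
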