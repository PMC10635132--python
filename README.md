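# moveindex

A move-structure full-text index for pangenomes, with a brute-force BWT
oracle it is verified against.

Pangenome collections — many near-identical genomes indexed jointly — are
highly repetitive, so the Burrows–Wheeler transform (BWT) of the
concatenated text contains few runs: `r ≪ n`. The **move structure**
exploits this by storing one table row per BWT run

```
row i:  (c, ℓ, p, π, ξ)      c = run character, ℓ = run length,
                             p = BWT offset of the run head,
                             π = LF[p],  ξ = run containing π
```

so one LF-mapping step — the backward step through the text that underlies
all BWT pattern matching — becomes pure row arithmetic

```
LF[j] = M[i].π + (j − M[i].p)
```

followed by a short forward scan ("fast-forward") from row `ξ` to the row
actually containing `LF[j]`. No rank/select bitvectors or wavelet trees are
involved, which is what makes the structure cache-friendly and its work per
query predictable.

Two modes are supported:

* **default** — the table as-is; fast-forward counts are unbounded in
  principle but instrumented and typically tiny;
* **constant** — runs are split (Nishimoto–Tabei) with a parameter `d ≥ 2`
  so every LF query performs strictly fewer than `2d` fast-forwards, and
  each row additionally stores, for every other base, pointers to the
  nearest run above and below carrying that base (six pointers per row for
  DNA), making the mismatch step constant-time too.

On top of LF the package answers:

* **PML queries** — pseudo matching lengths, a one-pass lower
  approximation of matching statistics: scanning the read right-to-left,
  a position whose BWT character matches extends the current match by one;
  a mismatch repositions the cursor to the nearest matching run — the
  direction chosen by a per-run *threshold* derived from LCP minima — and
  resets the length to 0. PMLs drive read classification, e.g. for
  nanopore adaptive sampling.
* **count queries** — classic backward search; the final interval width is
  the number of occurrences of the pattern.

Reads are processed by an interleaved round-robin driver (default 16
concurrent reads) whose inner loop issues a prefetch hint before each LF
destination access — the latency-hiding loop shape, implemented here with a
no-op hint and deterministic, order-independent results.

Everything is verified against brute-force oracles (suffix array, full LF
array, LCP, naive counting and matching statistics) built by the
`bwt_oracle` module, and a synthetic-pangenome generator makes the package
fully self-contained.

## Worked example

```
$ moveindex generate -o toy --base-length 2000 --haplotypes 5 \
      --n-reads 8 --read-len 80 --error-rate 0.02 --seed 42
seed 42: wrote 5 haplotypes to toy.refs.fa and 8 reads to toy.reads.fa

$ moveindex build -f toy.refs.fa -o toy.default.idx
built default index: n=10006 r=1591 rows=1591 n/r=6.29

$ moveindex build -f toy.refs.fa -o toy.constant.idx --mode constant --d 3
built constant index: n=10006 r=1591 rows=1592 n/r=6.29
run splitting d=3: row growth 1.001x (fast-forwards per LF bounded below 6)
```

`n` is the total text length (5 haplotypes plus separators and terminator),
`r` the number of BWT runs: `n/r ≈ 6.3` reflects the redundancy of five
near-identical haplotypes. Splitting with `d=3` added a single row here
while guaranteeing fewer than 6 fast-forwards per LF query.

```
$ moveindex query -i toy.default.idx -r toy.reads.fa -o toy.pml.txt --pml
processed 8 reads (pml); LF calls 640, fast-forwards 151 (max/call 3),
repositions 85 (scan steps 230, max 13)

$ head -2 toy.pml.txt
>read0
43 42 41 40 39 38 37 36 35 34 33 ... 3 2 1
```

The PML vector of `read0` descends from 43: the 43-base suffix starting at
read position 0 matches the pangenome exactly, and each later position has
one fewer matching base ahead of it. A sequencing error resets the count to
0 at the error position (see `read1` in the output).

```
$ moveindex query -i toy.default.idx -r toy.reads.fa -o toy.counts.tsv --count
$ head -4 toy.counts.tsv
read0	0
read1	3
read2	0
read3	4
```

Counts are exact-occurrence counts of the whole 80-bp read: reads carrying
a simulated error count 0, error-free reads count once per haplotype that
kept that locus unmutated.

The same things are available as a library:

```python
import moveindex as mi

text = mi.build_text([("chr", "ACGTACGTTACG")])
oracle = mi.build_oracle(text)                     # brute-force ground truth
table = mi.build_move_table(oracle, mode="constant", d=3)
mi.compute_pml(table, "GTTAC").lengths             # (5, 4, 3, 2, 1)
mi.backward_search_count(table, "ACG")             # 3
```

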