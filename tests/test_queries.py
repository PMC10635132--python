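"""PML and count queries, repositioning, and the interleaved batch driver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import moveindex as mi
from conftest import random_dna, random_text

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestReposition:
    def test_forced_down(self, acac_table):
        # terminator row: no A above, must jump down into the A-run
        assert mi.reposition(acac_table, mi.BiPointer(1, 2), "A") == mi.BiPointer(2, 3)

    def test_forced_up(self, acac_table):
        # bottom A-run: no C below, must jump up to the C-run's last offset
        assert mi.reposition(acac_table, mi.BiPointer(2, 3), "C") == mi.BiPointer(0, 1)

    def test_absent_character_signalled(self, acac_table):
        with pytest.raises(mi.CharacterAbsentError):
            mi.reposition(acac_table, mi.BiPointer(2, 3), "G")

    def test_scan_and_pointer_modes_agree_exhaustively(self, small_pangenome):
        _, _, default, constant = small_pangenome
        for j in range(default.n):
            run_d = mi.run_of_offset(default, j)
            run_c = mi.run_of_offset(constant, j)
            for a in mi.BASES:
                if default.rows[run_d].c == a:
                    continue
                got_d = mi.reposition(default, mi.BiPointer(run_d, j), a)
                got_c = mi.reposition(constant, mi.BiPointer(run_c, j), a)
                assert got_d.off == got_c.off
                # target really is the nearest occurrence of a
                assert default.rows[got_d.run].c == a


class TestComputePml:
    def test_absent_character_gives_zero_vector(self, acac_table):
        assert mi.compute_pml(acac_table, "GGGG").lengths == (0, 0, 0, 0)

    def test_n_treated_as_mismatch(self, small_pangenome):
        text, _, table, _ = small_pangenome
        seq = text.document(0)[:30]
        with_n = seq[:10] + "N" + seq[11:]
        vec = mi.compute_pml(table, with_n).lengths
        assert len(vec) == 30 and vec[10] == 0

    def test_exact_read_bounded_by_its_matching_statistics(self, small_pangenome):
        # PML approximates MS from below: an exact read has MS[0] = m, and
        # every PML stays within the corresponding matching statistic
        text, _, table, _ = small_pangenome
        seq = text.document(1)[40:90]
        vec = mi.compute_pml(table, seq).lengths
        ms = mi.matching_statistics_naive(text.text, seq)
        assert ms[0] == len(seq)
        assert all(v <= s for v, s in zip(vec, ms))
        assert max(vec) > 0

    def test_cross_mode_identity_and_soundness(self, small_pangenome):
        text, _, default, constant = small_pangenome
        reads = mi.generate_reads(
            text, 60, 80, error_rate=0.08, decoy_fraction=0.25, seed=13
        )
        for name, seq in reads:
            vec = mi.compute_pml(default, seq, name).lengths
            assert vec == mi.compute_pml(constant, seq, name).lengths
            assert len(vec) == len(seq)
            ms = mi.matching_statistics_naive(text.text, seq)
            for k, v in enumerate(vec):
                assert 0 <= v <= ms[k]
                if v > 0:
                    assert seq[k : k + v] in text.text
                if k + 1 < len(vec):
                    assert vec[k] <= vec[k + 1] + 1

    def test_empty_read_rejected(self, acac_table):
        with pytest.raises(ValueError):
            mi.compute_pml(acac_table, "")


class TestInitialRange:
    def test_single_character_block(self, acac_table):
        rng = mi.initial_range(acac_table, "A")
        assert (rng.top.off, rng.bottom.off) == (1, 2)

    def test_absent_character_is_empty(self, acac_table):
        assert mi.initial_range(acac_table, "G").empty

    def test_ranges_partition_the_bwm(self, small_pangenome):
        _, _, table, _ = small_pangenome
        covered = set()
        for a in mi.BASES:
            rng = mi.initial_range(table, a)
            if not rng.empty:
                covered |= set(range(rng.top.off, rng.bottom.off + 1))
        specials = table.n - sum(table.char_total(a) for a in mi.BASES)
        assert covered == set(range(specials, table.n))


class TestBackwardSearchCount:
    @pytest.mark.parametrize(
        "pattern,expected", [("AC", 2), ("ACAC", 1), ("G", 0), ("A", 2)]
    )
    def test_acac_examples(self, acac_table, pattern, expected):
        assert mi.backward_search_count(acac_table, pattern) == expected

    def test_non_base_pattern_rejected(self, acac_table):
        with pytest.raises(ValueError):
            mi.backward_search_count(acac_table, "AN")

    def test_oracle_equivalence_both_modes(self):
        rng = np.random.default_rng(71)
        text = random_text(rng, 500)
        oracle = mi.build_oracle(text)
        tables = [
            mi.build_move_table(oracle),
            mi.build_move_table(oracle, mode="constant", d=2),
        ]
        patterns = {text[i : i + L] for L in (1, 2, 4, 8) for i in range(0, 492, 7)}
        patterns |= {random_dna(rng, int(rng.integers(1, 12))) for _ in range(300)}
        for pattern in patterns:
            expected = mi.count_naive(text, pattern)
            for table in tables:
                assert mi.backward_search_count(table, pattern) == expected

    @given(dna, dna)
    def test_count_matches_naive(self, s, pattern):
        text = s + "$"
        table = mi.build_move_table(mi.build_oracle(text))
        assert mi.backward_search_count(table, pattern) == mi.count_naive(text, pattern)


@pytest.fixture(scope="module")
def reads(small_pangenome):
    text, _, _, _ = small_pangenome
    return list(
        mi.generate_reads(text, 40, 60, error_rate=0.05, decoy_fraction=0.2, seed=5)
    )


class TestProcessBatch:
    def test_batch_one_equals_sequential(self, small_pangenome, reads):
        _, _, table, _ = small_pangenome
        results = mi.process_batch(table, reads, query="pml", batch_size=1)
        for (name, seq), vec in zip(reads, results):
            assert vec == mi.compute_pml(table, seq, name)

    @pytest.mark.parametrize("query", ["pml", "count"])
    @pytest.mark.parametrize("batch_size", [2, 16, 32])
    def test_batch_size_invariance(self, small_pangenome, reads, query, batch_size):
        _, _, table, _ = small_pangenome
        baseline = mi.process_batch(table, reads, query=query, batch_size=1)
        assert mi.process_batch(table, reads, query=query, batch_size=batch_size) == baseline

    def test_read_set_smaller_than_batch(self, small_pangenome, reads):
        _, _, table, _ = small_pangenome
        few = reads[:3]
        results = mi.process_batch(table, few, query="pml", batch_size=16)
        assert [v.name for v in results] == [name for name, _ in few]

    def test_counts_from_exact_reads_are_positive(self, small_pangenome):
        text, _, table, _ = small_pangenome
        exact = list(mi.generate_reads(text, 25, 40, error_rate=0.0, seed=3))
        for name, count in mi.process_batch(table, exact, query="count", batch_size=16):
            assert count >= 1, name

    def test_invalid_batch_size(self, small_pangenome, reads):
        _, _, table, _ = small_pangenome
        with pytest.raises(ValueError):
            mi.process_batch(table, reads, batch_size=0)


class TestInstrumentation:
    def test_constant_mode_ops_bounded_default_mode_logged(self, small_pangenome):
        text, _, default, constant = small_pangenome
        reads = list(mi.generate_reads(text, 30, 60, error_rate=0.1, seed=21))
        constant.counters.reset()
        default.counters.reset()
        mi.process_batch(constant, reads, query="pml", batch_size=16)
        mi.process_batch(default, reads, query="pml", batch_size=16)
        d = constant.d
        assert constant.counters.max_fast_forwards < 2 * d
        assert constant.counters.max_reposition_scans == 0  # pointer lookups
        assert default.counters.lf_calls > 0
        assert default.counters.max_fast_forwards >= 0  # unbounded but recorded
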