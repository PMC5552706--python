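"""Entropy computation, decomposition, position selection and the M filter."""

from __future__ import annotations

import math
from collections import Counter, defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligotyper import oligotypes as olig

from conftest import make_reads


def shannon_bits(counts):
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c)


class TestColumnEntropy:
    def test_monomorphic_column_is_zero(self):
        rs = make_reads(["A", "A", "A"])
        assert olig.column_entropy(rs, 0) == 0.0

    def test_symmetric_binary_column_is_one_bit(self):
        rs = make_reads(["A", "A", "C", "C"])
        assert olig.column_entropy(rs, 0) == pytest.approx(1.0)

    def test_skewed_column_matches_direct_formula(self):
        # A:70, C:20, T:10 -> 1.157 bits
        rs = make_reads(["A"] * 70 + ["C"] * 20 + ["T"] * 10)
        expected = shannon_bits([70, 20, 10])
        assert olig.column_entropy(rs, 0) == pytest.approx(expected, abs=1e-12)
        assert round(expected, 3) == 1.157

    def test_n_excluded_from_numerator_and_denominator(self):
        # A:2, N:2 -> the counted distribution is pure A
        rs = make_reads(["A", "A", "N", "N"])
        assert olig.column_entropy(rs, 0) == 0.0
        # A:1, C:1, N:2 -> 1 bit over the two counted characters
        rs = make_reads(["A", "C", "N", "N"])
        assert olig.column_entropy(rs, 0) == pytest.approx(1.0)

    def test_all_n_column_warns_and_returns_zero(self):
        rs = make_reads(["N", "N"])
        with pytest.warns(UserWarning, match="only N"):
            assert olig.column_entropy(rs, 0) == 0.0

    def test_gap_counts_as_fifth_character(self):
        rs = make_reads(["A", "-"])
        assert olig.column_entropy(rs, 0) == pytest.approx(1.0)

    def test_out_of_range_column(self):
        with pytest.raises(IndexError):
            olig.column_entropy(make_reads(["AC"]), 2)


class TestEntropyProfile:
    def test_identical_reads_give_zero_profile(self):
        profile = olig.entropy_profile(make_reads(["ACGT"] * 5))
        assert np.allclose(profile, 0.0)

    def test_single_variable_column(self):
        profile = olig.entropy_profile(make_reads(["ACGT", "ACCT"]))
        assert profile[2] == pytest.approx(1.0)
        assert np.allclose(np.delete(profile, 2), 0.0)

    def test_profile_length_matches_alignment(self):
        rs = make_reads(["ACG-TN" * 3] * 4)
        assert olig.entropy_profile(rs).shape == (rs.alignment_length,)

    def test_empty_read_set_errors(self):
        with pytest.raises(ValueError):
            olig.entropy_profile(make_reads([]))

    def test_bounds(self):
        rs = make_reads(["A", "C", "G", "T", "-"])
        profile = olig.entropy_profile(rs)
        assert 0.0 <= profile[0] <= math.log2(5) + 1e-12


def brute_force_partition(rs, positions):
    """Independent group-by on the position string key."""
    groups = defaultdict(list)
    for i, seq in enumerate(rs.sequences()):
        key = "".join(seq[p] for p in positions)
        groups[key].append(i)
    return groups


class TestDecompose:
    def test_no_positions_yields_single_oligotype(self):
        rs = make_reads(["ACGT", "TTTT", "ACGA"])
        part = olig.decompose(rs, [])
        assert len(part.oligotypes) == 1
        assert part.oligotypes[0].code == ""
        assert part.oligotypes[0].total_count == 3

    def test_manual_grouping_example(self):
        # position-strings at columns {3, 7}: AA x3, AG x2, CA x1
        reads = [
            "TTTATTTAT",
            "TTTATTTAT",
            "TTTATTTAT",
            "TTTATTTGT",
            "TTTATTTGT",
            "TTTCTTTAT",
        ]
        rs = make_reads(reads)
        part = olig.decompose(rs, [3, 7])
        assert [o.code for o in part.oligotypes] == ["AA", "AG", "CA"]
        assert [o.total_count for o in part.oligotypes] == [3, 2, 1]

    def test_all_columns_equals_dereplication(self):
        from oligotyper.sequence_io import dereplicate

        rs = make_reads(["ACGT", "ACGT", "ACGA", "TCGA"])
        part = olig.decompose(rs, list(range(4)))
        tally = dereplicate(rs)
        assert [o.code for o in part.oligotypes] == tally.sequences
        assert [o.total_count for o in part.oligotypes] == list(tally.counts)

    @given(
        st.lists(st.text(alphabet="ACGT-N", min_size=8, max_size=8),
                 min_size=1, max_size=60),
        st.sets(st.integers(min_value=0, max_value=7), max_size=4),
        st.integers(min_value=1, max_value=5),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_and_conserves(self, seqs, pos_set, m):
        positions = sorted(pos_set)
        samples = [f"s{i % 3}" for i in range(len(seqs))]
        rs = make_reads(seqs, samples=samples)
        part = olig.decompose(rs, positions)
        expected = brute_force_partition(rs, positions)
        got = {o.code: sorted(o.read_indices.tolist()) for o in part.oligotypes}
        assert got == {k: sorted(v) for k, v in expected.items()}
        filtered = olig.apply_min_substantive_abundance(part, m)
        for p in (part, filtered):
            acc = Counter(p.other_bucket)
            for o in p.oligotypes:
                acc.update(o.sample_counts)
            assert acc == Counter(samples)

    def test_adding_position_never_decreases_group_count(self):
        rs = make_reads(["ACGT", "ACCA", "TCGA", "ACGT", "TCCT"])
        for base in ([], [0], [0, 2]):
            n_before = len(olig.decompose(rs, base).oligotypes)
            for extra in range(4):
                if extra in base:
                    continue
                n_after = len(olig.decompose(rs, base + [extra]).oligotypes)
                assert n_after >= n_before


class TestMinSubstantiveAbundance:
    def _partition_with_top_counts(self, *top_counts):
        """One oligotype per requested top-unique-sequence count."""
        seqs, samples = [], []
        for i, c in enumerate(top_counts):
            # base character at column 0 keys the oligotype
            key = "ACGT"[i]
            seqs += [key + "AAA"] * c + [key + "AAT"]  # one minor member each
            samples += ["s"] * (c + 1)
        rs = make_reads(seqs, samples=samples)
        return olig.decompose(rs, [0])

    def test_boundary_at_m_equals_20(self):
        part = self._partition_with_top_counts(19, 20)
        filtered = olig.apply_min_substantive_abundance(part, 20)
        assert [o.substantive_abundance for o in filtered.oligotypes] == [20]
        # dissolved reads all moved to the other bucket
        assert filtered.other_bucket["s"] == 20  # 19 + 1 minor member
        filtered.check_conservation()

    def test_m_of_one_is_identity(self):
        part = self._partition_with_top_counts(5, 3)
        filtered = olig.apply_min_substantive_abundance(part, 1)
        assert len(filtered.oligotypes) == len(part.oligotypes)
        assert filtered.other_bucket == Counter()

    def test_dissolved_oligotype_moves_entirely_to_other(self):
        part = self._partition_with_top_counts(25, 5)
        filtered = olig.apply_min_substantive_abundance(part, 20)
        assert len(filtered.oligotypes) == 1
        assert filtered.oligotypes[0].substantive_abundance == 25
        assert filtered.other_bucket["s"] == 6  # 5 + its minor member

    def test_raising_m_never_increases_oligotypes(self):
        part = self._partition_with_top_counts(30, 20, 10, 2)
        sizes = [
            len(olig.apply_min_substantive_abundance(part, m).oligotypes)
            for m in (1, 5, 15, 25, 40)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            olig.apply_min_substantive_abundance(self._partition_with_top_counts(3), 0)


class TestRepresentative:
    def test_single_member(self):
        part = olig.decompose(make_reads(["ACGT"] * 3), [0])
        assert olig.representative_sequence(part.oligotypes[0]) == "ACGT"

    def test_most_abundant_member_wins(self):
        rs = make_reads(["AAAA"] * 10 + ["AAAT"] * 3)
        part = olig.decompose(rs, [0])
        assert olig.representative_sequence(part.oligotypes[0]) == "AAAA"
        assert part.oligotypes[0].substantive_abundance == 10

    def test_tie_breaks_lexicographically(self):
        rs = make_reads(["TAAA"] * 5 + ["TCCC"] * 5)
        part = olig.decompose(rs, [0])
        assert olig.representative_sequence(part.oligotypes[0]) == "TAAA"

    def test_empty_oligotype_errors(self):
        o = olig.Oligotype(code="", read_indices=np.empty(0, int),
                           sample_counts=Counter(), members=[])
        with pytest.raises(ValueError):
            olig.representative_sequence(o)


class TestSelectPositions:
    def test_identical_reads_select_nothing(self):
        ps = olig.select_positions(make_reads(["ACGT"] * 30), min_group_size=1)
        assert ps.positions == []

    def test_two_variants_single_discriminating_column(self):
        rs = make_reads(["ACGTACGT"] * 15 + ["ACGAACGT"] * 10)
        ps = olig.select_positions(rs, min_group_size=1)
        assert ps.positions == [3]
        part = olig.decompose(rs, ps.positions)
        assert len(part.oligotypes) == 2
        # after selection, all within-oligotype entropy is zero
        for o in part.oligotypes:
            sub = rs.subset(o.read_indices)
            assert np.allclose(olig.entropy_profile(sub), 0.0)

    def test_max_positions_cap(self):
        # every column polymorphic: random small alignment
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(40)]
        ps = olig.select_positions(make_reads(seqs), max_positions=19, min_group_size=1)
        assert len(ps.positions) <= 19
        assert len(set(ps.positions)) == len(ps.positions)

    def test_trace_records_iterations(self):
        rs = make_reads(["AC", "AT", "GC", "GT"] * 10)
        ps = olig.select_positions(rs, min_group_size=1)
        assert [t["position"] for t in ps.trace] == ps.positions
        assert all(t["entropy"] >= olig.DEFAULT_EPSILON for t in ps.trace)

    def test_invalid_parameters(self):
        rs = make_reads(["AC", "AT"])
        with pytest.raises(ValueError):
            olig.select_positions(rs, epsilon=0.0)
        with pytest.raises(ValueError):
            olig.select_positions(rs, max_positions=0)
        with pytest.raises(ValueError):
            olig.select_positions(make_reads([]))
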