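from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gkmloc import (
    DEFAULT_SCHEME,
    Vocabulary,
    build_multitree,
    build_vocabulary,
    collapse_multitree,
    count_gapped,
    count_kmers,
    enumerate_gap_sets,
    full_dimension,
    gapped_counts_via_trie,
    reduce_sequence,
    vectorize,
)
from gkmloc.features import feature_matrix

from conftest import make_rseq

ALPHABETS = {2: ("B", "W"), 6: DEFAULT_SCHEME.class_alphabet}


@st.composite
def reduced_seq_and_kg(draw, max_len=60, max_k=6):
    t = draw(st.sampled_from([2, 6]))
    alphabet = ALPHABETS[t]
    symbols = draw(st.text(alphabet="".join(alphabet), min_size=0, max_size=max_len))
    k = draw(st.integers(1, max_k))
    g = draw(st.integers(0, k))
    return make_rseq(symbols, alphabet), k, g


class TestCountKmers:
    def test_worked_example_five_types(self, paper_reduced):
        table = count_kmers(paper_reduced, 3)
        assert table.counts == {"LBB": 1, "BBB": 1, "BBW": 1, "BWW": 1, "WWG": 1}
        assert len(table.counts) == 5

    def test_binary_example_window_enumeration(self, binary_reduced):
        table = count_kmers(binary_reduced, 3)
        assert table.counts == {"BBB": 1, "BBW": 2, "BWW": 1, "WWB": 1,
                                "WBB": 1, "BWB": 1}
        assert table.window_total == 7  # l - k + 1

    def test_short_sequence_gives_empty_table(self):
        table = count_kmers(make_rseq("BB", ("B", "W")), 3)
        assert table.counts == {} and table.window_total == 0

    def test_k_below_one_rejected(self, paper_reduced):
        with pytest.raises(ValueError):
            count_kmers(paper_reduced, 0)

    def test_skip_marker_excludes_touching_windows(self):
        rseq = reduce_sequence("AAXAAAA", unknown_policy="skip")
        table = count_kmers(rseq, 3)
        # windows 0-2,1-3,2-4 touch the marker; 3-5 and 4-6 are clean
        assert table.window_total == 2
        assert table.counts == {"BBB": 2}


class TestGapSets:
    def test_single_gap_positions(self):
        assert enumerate_gap_sets(3, 1) == [(0,), (1,), (2,)]

    def test_pair_dimension(self):
        assert enumerate_gap_sets(2, 1) == [(0,), (1,)]
        assert full_dimension(6, 2, 1) == 12

    def test_zero_gaps_single_empty_set(self):
        assert enumerate_gap_sets(5, 0) == [()]

    def test_too_many_gaps_rejected(self):
        with pytest.raises(ValueError):
            enumerate_gap_sets(3, 4)


class TestCountGapped:
    def test_worked_example_twelve_patterns(self, paper_reduced):
        table = count_gapped(paper_reduced, 3, 1)
        expected = {"_BB", "_BW", "_WW", "_WG", "L_B", "B_W", "W_G", "B_B",
                    "LB_", "BB_", "BW_", "WW_"}
        assert set(table.counts) == expected
        assert len(table.counts) == 12

    def test_binary_example_middle_gap_count(self, binary_reduced):
        assert count_gapped(binary_reduced, 3, 1)["B_B"] == 2

    def test_zero_gaps_specializes_to_kmers(self, binary_reduced):
        assert count_gapped(binary_reduced, 3, 0).counts == \
            count_kmers(binary_reduced, 3).counts

    def test_all_gap_pattern_is_window_count(self, binary_reduced):
        table = count_gapped(binary_reduced, 3, 3)
        assert table.counts == {"___": 7}

    @given(case=reduced_seq_and_kg())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_count_conservation(self, case):
        """Every valid window contributes once per gap placement, so the
        counts sum to C(k, g) * (l - k + 1) on clean input."""
        rseq, k, g = case
        table = count_gapped(rseq, k, g)
        windows = max(0, len(rseq) - k + 1)
        assert table.total() == comb(k, g) * windows
        assert table.total() == table.window_total


class TestMultiTree:
    def test_leaf_counts_match_kmer_table(self, binary_reduced):
        tree = build_multitree(binary_reduced, 3)
        assert tree.n_leaves() == 6
        assert tree.leaf_table().counts == count_kmers(binary_reduced, 3).counts
        assert tree.root.subtree_count() == 7

    def test_single_count_leaves(self, paper_reduced):
        tree = build_multitree(paper_reduced, 3)
        assert tree.n_leaves() == 5
        assert all(c == 1 for c in tree.leaf_table().counts.values())

    def test_empty_sequence_root_only(self):
        tree = build_multitree(make_rseq("", ("B", "W")), 3)
        assert tree.n_leaves() == 0 and not tree.root.children

    def test_middle_layer_merge(self, binary_reduced):
        tree = build_multitree(binary_reduced, 3)
        assert collapse_multitree(tree, (1,)).counts == \
            {"B_B": 2, "B_W": 3, "W_B": 2}

    def test_head_node_elimination(self, paper_reduced):
        tree = build_multitree(paper_reduced, 3)
        assert collapse_multitree(tree, (0,)).counts == \
            {"_BB": 2, "_BW": 1, "_WW": 1, "_WG": 1}

    def test_empty_gap_set_is_identity(self, binary_reduced):
        tree = build_multitree(binary_reduced, 3)
        assert collapse_multitree(tree, ()).counts == \
            count_kmers(binary_reduced, 3).counts

    def test_gap_position_beyond_depth_rejected(self, binary_reduced):
        tree = build_multitree(binary_reduced, 3)
        with pytest.raises(ValueError):
            collapse_multitree(tree, (3,))

    @given(case=reduced_seq_and_kg(max_len=40, max_k=5))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_marginalization_identity(self, case):
        """Gapping one more position sums counts over the symbols that
        could fill it — the subtree-merge identity."""
        rseq, k, g = case
        if g == k:
            g = k - 1
        if g < 0:
            return
        base_sets = enumerate_gap_sets(k, g)
        gs = base_sets[0]
        extra = next(i for i in range(k) if i not in gs)
        tree = build_multitree(rseq, k)
        fine = collapse_multitree(tree, gs).counts
        coarse = collapse_multitree(tree, gs + (extra,)).counts
        for pattern, c in coarse.items():
            summed = sum(
                cnt for p, cnt in fine.items()
                if all(p[i] == pattern[i] for i in range(k) if i != extra)
            )
            assert summed == c


class TestTrieOracle:
    @given(case=reduced_seq_and_kg(max_len=80))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_trie_equals_sliding_window(self, case):
        """The single-trie collapse route must agree element-wise with
        direct sliding-window enumeration."""
        rseq, k, g = case
        brute = count_gapped(rseq, k, g)
        trie = gapped_counts_via_trie(rseq, k, g)
        assert trie.counts == brute.counts
        assert trie.window_total == brute.window_total


class TestDimensionAndVocabulary:
    @pytest.mark.parametrize("t,k,g,expected", [
        (6, 3, 1, 108), (6, 2, 1, 12), (6, 4, 2, 216),
        (6, 5, 3, 360), (6, 6, 4, 540), (6, 3, 0, 216), (6, 2, 0, 36),
    ])
    def test_dimension_formula(self, t, k, g, expected):
        assert full_dimension(t, k, g) == expected

    def test_invalid_ranges_rejected(self):
        for t, k, g in [(0, 3, 1), (6, 0, 0), (6, 3, 4), (6, 3, -1)]:
            with pytest.raises(ValueError):
                full_dimension(t, k, g)

    def test_full_vocabulary_size_exhaustive(self):
        """|full vocabulary| = C(k,g) * t**(k-g) over the whole small grid."""
        for t in range(2, 9):
            alphabet = tuple("abcdefgh"[:t])
            for k in range(1, 7):
                for g in range(0, k + 1):
                    vocab = build_vocabulary([], mode="full", alphabet=alphabet,
                                             k=k, g=g)
                    assert len(vocab) == full_dimension(t, k, g), (t, k, g)

    def test_observed_vocabulary_from_worked_example(self, paper_reduced):
        table = count_gapped(paper_reduced, 3, 1)
        vocab = build_vocabulary([table], mode="observed",
                                 alphabet=paper_reduced.alphabet)
        assert len(vocab) == 12

    def test_observed_subset_of_full_with_equality_when_saturated(self):
        # de-Bruijn-style: BBWWB contains every 2-mer over {B, W}
        rseq = make_rseq("BBWWB", ("B", "W"))
        for g in (0, 1):
            table = count_gapped(rseq, 2, g)
            observed = build_vocabulary([table], mode="observed",
                                        alphabet=rseq.alphabet)
            full = build_vocabulary([table], mode="full", alphabet=rseq.alphabet)
            assert set(observed.patterns) <= set(full.patterns)
            assert observed.patterns == full.patterns

    def test_empty_table_list_observed_empty(self):
        assert len(build_vocabulary([], mode="observed")) == 0

    def test_mixed_kg_rejected(self, paper_reduced):
        with pytest.raises(ValueError, match="mixed"):
            build_vocabulary([count_kmers(paper_reduced, 2),
                              count_kmers(paper_reduced, 3)])

    def test_ordering_alphabet_first_gap_last(self):
        vocab = build_vocabulary([], mode="full", alphabet=("B", "W"), k=2, g=1)
        assert vocab.patterns == ("B_", "W_", "_B", "_W")


class TestVectorize:
    def test_projection_with_missing_and_extra_patterns(self, binary_reduced):
        tree = build_multitree(binary_reduced, 3)
        table = collapse_multitree(tree, (1,))  # {B_B:2, B_W:3, W_B:2}
        vocab = Vocabulary(patterns=("B_B", "B_W", "W_B", "W_W"),
                           mode="observed", k=3, g=1, alphabet=("B", "W"))
        vec = vectorize(table, vocab, "counts")
        assert vec.values.tolist() == [2.0, 3.0, 2.0, 0.0]

    def test_frequency_normalization_sums_to_one(self, binary_reduced):
        table = count_gapped(binary_reduced, 3, 1)
        vocab = build_vocabulary([table], mode="observed",
                                 alphabet=binary_reduced.alphabet)
        vec = vectorize(table, vocab, "frequency")
        assert vec.values.sum() == pytest.approx(1.0)

    def test_empty_table_gives_zero_vector(self):
        empty = count_kmers(make_rseq("", ("B", "W")), 3)
        vocab = build_vocabulary([], mode="full", alphabet=("B", "W"), k=3, g=0)
        vec = vectorize(empty, vocab)
        assert not vec.values.any() and len(vec.values) == 8

    def test_mismatched_kg_rejected(self, binary_reduced):
        table = count_kmers(binary_reduced, 3)
        vocab = build_vocabulary([], mode="full", alphabet=("B", "W"), k=2, g=0)
        with pytest.raises(ValueError):
            vectorize(table, vocab)


def test_feature_matrix_stacks_rows(paper_reduced, binary_reduced):
    rseq2 = make_rseq("LBBBWWG", DEFAULT_SCHEME.class_alphabet)
    X, vocab = feature_matrix([paper_reduced, rseq2], k=3, g=1, mode="observed")
    assert X.shape == (2, 12)
    assert np.array_equal(X[0], X[1])
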