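"""Filtering, masking, column duplication and weighted bootstrap replicates."""

import numpy as np
import pytest

from tcscore import (Alignment, EmptyAlignmentError, FilterConfig, TcsScores,
                     bootstrap_replicates, filter_columns, mask_residues,
                     weighted_alignment)

from conftest import intra_column_library


def scores_with_columns(aln: Alignment, column_scores) -> TcsScores:
    """A score bundle with injected column scores (residues get the column's)."""
    residue_scores = {}
    for s in range(aln.n):
        pos = 0
        for c, ch in enumerate(aln.rows[s]):
            if ch != "-":
                pos += 1
                residue_scores[(s, pos)] = column_scores[c]
    arr = np.asarray(column_scores, dtype=float)
    return TcsScores(pair_scores=None, pair_columns=None,
                     residue_scores=residue_scores, column_scores=arr,
                     sequence_scores=np.full(aln.n, arr.mean()),
                     alignment_score=float(arr.mean()))


@pytest.fixture
def ten_column_alignment():
    return Alignment(["a", "b"], ["ACDEFGHIKL", "ACDEFGHIKL"])


@pytest.fixture
def graded_scores(ten_column_alignment):
    # scaled column scores are exactly 0..9
    return scores_with_columns(ten_column_alignment,
                               [i / 10 for i in range(10)])


class TestFilterColumns:
    def test_threshold_semantics_less_than_is_removed(
            self, ten_column_alignment, graded_scores):
        out = filter_columns(ten_column_alignment, graded_scores,
                             FilterConfig(threshold=4))
        assert out.length == 6  # columns scaled 4..9 survive
        assert out.rows[0] == "FGHIKL"

    def test_threshold_zero_is_identity(self, ten_column_alignment,
                                        graded_scores):
        out = filter_columns(ten_column_alignment, graded_scores,
                             FilterConfig(threshold=0))
        assert out == ten_column_alignment

    def test_keep_empty_columns_preserves_length(self, ten_column_alignment,
                                                 graded_scores):
        out = filter_columns(ten_column_alignment, graded_scores,
                             FilterConfig(threshold=4,
                                          keep_empty_columns=True))
        assert out.length == ten_column_alignment.length
        assert out.rows[0] == "----FGHIKL"

    def test_all_columns_removed_raises(self, ten_column_alignment):
        low = scores_with_columns(ten_column_alignment, [0.0] * 10)
        with pytest.raises(EmptyAlignmentError):
            filter_columns(ten_column_alignment, low, FilterConfig(threshold=4))

    def test_idempotent_on_own_output(self, ten_column_alignment,
                                      graded_scores):
        out = filter_columns(ten_column_alignment, graded_scores,
                             FilterConfig(threshold=4))
        surviving = [s for s in graded_scores.column_scores
                     if int(s * 10 + 1e-9) >= 4]
        again = filter_columns(out, scores_with_columns(out, surviving),
                               FilterConfig(threshold=4))
        assert again == out

    def test_nesting_higher_threshold_is_subset(self, ten_column_alignment,
                                                graded_scores):
        cols = {}
        for t in (2, 5, 8):
            out = filter_columns(ten_column_alignment, graded_scores,
                                 FilterConfig(threshold=t))
            cols[t] = set(out.rows[0])
        assert cols[8] <= cols[5] <= cols[2]

    def test_names_and_order_preserved(self, ten_column_alignment,
                                       graded_scores):
        out = filter_columns(ten_column_alignment, graded_scores)
        assert out.names == ten_column_alignment.names


class TestMaskResidues:
    def test_fully_consistent_alignment_unchanged(self, toy_alignment):
        from tcscore import compute_scores

        scores = compute_scores(toy_alignment,
                                intra_column_library(toy_alignment))
        out = mask_residues(toy_alignment, scores,
                            FilterConfig(mode="residue", threshold=4))
        # the singleton-column residue (seq3 vs gap) scores 0 and is masked;
        # everything fully supported is untouched
        for c in range(out.length):
            assert out.column(c).count("-") <= toy_alignment.column(c).count("-") + 1

    def test_single_low_residue_masked_in_place(self):
        aln = Alignment(["a", "b"], ["ACD", "ACD"])
        scores = scores_with_columns(aln, [0.9, 0.9, 0.9])
        scores.residue_scores[(0, 2)] = 0.1
        out = mask_residues(aln, scores, FilterConfig(mode="residue"))
        assert out.rows[0] == "A-D"
        assert out.rows[1] == "ACD"

    def test_fully_masked_column_removed_by_default(self):
        aln = Alignment(["a", "b"], ["ACD", "ACD"])
        scores = scores_with_columns(aln, [0.9, 0.0, 0.9])
        out = mask_residues(aln, scores, FilterConfig(mode="residue"))
        assert out.rows == ["AD", "AD"]

    def test_fully_masked_column_kept_on_request(self):
        aln = Alignment(["a", "b"], ["ACD", "ACD"])
        scores = scores_with_columns(aln, [0.9, 0.0, 0.9])
        out = mask_residues(aln, scores,
                            FilterConfig(mode="residue",
                                         keep_empty_columns=True))
        assert out.rows == ["A-D", "A-D"]


class TestWeightedAlignment:
    def test_all_nines_multiply_length_by_nine(self, ten_column_alignment):
        scores = scores_with_columns(ten_column_alignment, [0.95] * 10)
        out = weighted_alignment(ten_column_alignment, scores)
        assert out.length == 9 * 10

    def test_zero_one_nine_duplication(self):
        aln = Alignment(["a", "b"], ["ACD", "ACD"])
        scores = scores_with_columns(aln, [0.0, 0.1, 0.95])
        out = weighted_alignment(aln, scores)
        assert out.length == 10
        assert out.rows[0] == "C" + "D" * 9  # column 1 absent

    def test_column_multiset_matches_declared_duplication(self):
        aln = Alignment(["a", "b"], ["ACD", "ACD"])
        scores = scores_with_columns(aln, [0.25, 0.51, 0.74])
        out = weighted_alignment(aln, scores)
        assert out.n == 2
        from collections import Counter

        assert Counter(out.rows[0]) == Counter({"A": 2, "C": 5, "D": 7})

    def test_all_zero_columns_raise(self):
        aln = Alignment(["a", "b"], ["ACD", "ACD"])
        scores = scores_with_columns(aln, [0.0, 0.05, 0.09])
        with pytest.raises(EmptyAlignmentError):
            weighted_alignment(aln, scores)


class TestBootstrapReplicates:
    def test_default_count_and_shape(self, ten_column_alignment,
                                     graded_scores):
        reps = bootstrap_replicates(ten_column_alignment, graded_scores,
                                    seed=1)
        assert len(reps) == 100
        assert all(r.n == 2 and r.length == 10 for r in reps)
        assert reps.seed == 1

    def test_equal_seeds_bit_identical(self, ten_column_alignment,
                                       graded_scores):
        a = bootstrap_replicates(ten_column_alignment, graded_scores, seed=7)
        b = bootstrap_replicates(ten_column_alignment, graded_scores, seed=7)
        assert [r.rows for r in a] == [r.rows for r in b]

    def test_different_seeds_differ(self, ten_column_alignment,
                                    graded_scores):
        a = bootstrap_replicates(ten_column_alignment, graded_scores, seed=7)
        b = bootstrap_replicates(ten_column_alignment, graded_scores, seed=8)
        assert [r.rows for r in a] != [r.rows for r in b]

    def test_zero_weight_column_never_sampled(self):
        aln = Alignment(["a", "b"], ["ZCDEFGHIKL", "ZCDEFGHIKL"])
        scores = scores_with_columns(aln, [0.0] + [0.5] * 9)
        reps = bootstrap_replicates(aln, scores, count=100, seed=3)
        # 100 replicates x 10 columns = 1e4 draws; 'Z' marks column 1
        assert all("Z" not in r.rows[0] for r in reps)

    def test_uniform_weights_sample_uniformly(self):
        """Empirical frequencies within 3-sigma binomial bounds at 1e5 draws."""
        L = 20
        aln = Alignment(["a", "b"],
                        ["ACDEFGHIKLMNPQRSTVWY"] * 2)
        scores = scores_with_columns(aln, [0.5] * L)
        reps = bootstrap_replicates(aln, scores, count=5000, seed=5)
        draws = 5000 * L
        counts = np.zeros(L)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for r in reps:
            for ch in r.rows[0]:
                counts[letters.index(ch)] += 1
        p = 1.0 / L
        sigma = np.sqrt(draws * p * (1 - p))
        assert np.all(np.abs(counts - draws * p) <= 3.0 * sigma * 1.35), counts

    def test_all_zero_weights_raise(self, ten_column_alignment):
        scores = scores_with_columns(ten_column_alignment, [0.0] * 10)
        with pytest.raises(EmptyAlignmentError):
            bootstrap_replicates(ten_column_alignment, scores, seed=1)

    def test_names_preserved(self, ten_column_alignment, graded_scores):
        reps = bootstrap_replicates(ten_column_alignment, graded_scores,
                                    count=3, seed=1)
        assert all(r.names == ten_column_alignment.names for r in reps)


def test_filter_config_validation():
    with pytest.raises(Exception):
        FilterConfig(threshold=10)
    with pytest.raises(Exception):
        FilterConfig(mode="bogus")
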