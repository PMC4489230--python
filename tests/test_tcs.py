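"""Transitive consistency scoring against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from tcscore import (Alignment, TcsError, compute_scores, pair_tcs,
                     residue_tcs, column_tcs, scale_to_0_9)
from tcscore.alignment import column_residue_table

from conftest import intra_column_library, random_alignment, random_library
from test_library import make_library


def oracle_pair_tcs(lib, x, i, y, j):
    """Unoptimised triple loop over every residue of every third sequence.

    Numerator: direct weight plus, per third-sequence residue, the smaller
    of its two link weights; denominator: direct weight plus the larger of
    the two link weights per third-sequence residue, plus all conflicting
    links of either residue (including links to other positions of the
    partner sequence).
    """
    direct = lib.weight(x, i, y, j)
    num = den = direct
    for z in range(len(lib.sequences)):
        if z in (x, y):
            continue
        for k in range(1, len(lib.sequences[z]) + 1):
            wx = lib.weight(x, i, z, k)
            wy = lib.weight(z, k, y, j)
            num += min(wx, wy)
            den += max(wx, wy)
    for q in range(1, len(lib.sequences[y]) + 1):
        if q != j:
            den += lib.weight(x, i, y, q)
    for q in range(1, len(lib.sequences[x]) + 1):
        if q != i:
            den += lib.weight(x, q, y, j)
    return num / den if den > 0 else 0.0


class TestPairTcs:
    def test_hand_enumerated_three_sequence_case(self):
        """One intermediate: num = 0.9 + min(.8,.6), den = 0.9 + max(.8,.6)."""
        lib = make_library([(0, 1, 1, 1, 0.9), (0, 1, 2, 1, 0.8),
                            (2, 1, 1, 1, 0.6)],
                           seqs=("A", "A", "A"))
        expected = (0.9 + 0.6) / (0.9 + 0.8)
        assert pair_tcs(lib, 0, 1, 1, 1) == pytest.approx(expected)
        assert oracle_pair_tcs(lib, 0, 1, 1, 1) == pytest.approx(expected)

    def test_no_support_scores_zero(self):
        lib = make_library([])
        assert pair_tcs(lib, 0, 1, 1, 1) == 0.0

    def test_unmatched_partner_entries_only_penalise(self):
        # y1 has one link to z1; x1 has none: numerator stays 0
        lib = make_library([(1, 1, 2, 1, 0.5)], seqs=("A", "A", "A"))
        assert pair_tcs(lib, 0, 1, 1, 1) == 0.0

    def test_same_sequence_pair_rejected(self):
        lib = make_library([])
        with pytest.raises(TcsError):
            pair_tcs(lib, 0, 1, 0, 2)

    def test_out_of_msa_coordinates_rejected(self):
        lib = make_library([])
        with pytest.raises(TcsError):
            pair_tcs(lib, 0, 99, 1, 1)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, 4, 6)
        lib = random_library(rng, aln)
        for (x, i), (y, j) in itertools.combinations(
                [(s, p) for s in range(aln.n)
                 for p in range(1, len(lib.sequences[s]) + 1)], 2):
            if x == y:
                continue
            assert pair_tcs(lib, x, i, y, j) == \
                pytest.approx(pair_tcs(lib, y, j, x, i), abs=1e-15)

    def test_adding_unmatched_entry_strictly_decreases_score(self):
        entries = [(0, 1, 1, 1, 0.9), (0, 1, 2, 1, 0.8), (2, 1, 1, 1, 0.6)]
        lib = make_library(entries, seqs=("AA", "AA", "AA"))
        before = pair_tcs(lib, 0, 1, 1, 1)
        lib.add(0, 1, 2, 2, 0.5)  # z2 has no link to y1
        after = pair_tcs(lib, 0, 1, 1, 1)
        assert after < before

    def test_oracle_equivalence_on_random_instances(self):
        """Production scorer equals the triple-loop oracle, 200 instances."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 6))
            L = int(rng.integers(2, 9))
            aln = random_alignment(rng, n, L)
            lib = random_library(rng, aln, n_entries=int(rng.integers(5, 60)))
            for residues in column_residue_table(aln):
                for (x, i), (y, j) in itertools.combinations(residues, 2):
                    got = pair_tcs(lib, x, i, y, j)
                    want = oracle_pair_tcs(lib, x, i, y, j)
                    assert got == pytest.approx(want, abs=1e-12)


class TestDerivedScores:
    def test_fully_consistent_limit_all_scores_one(self, toy_alignment):
        lib = intra_column_library(toy_alignment)
        scores = compute_scores(toy_alignment, lib)
        assert all(v == pytest.approx(1.0)
                   for v in scores.residue_scores.values())
        present = [c for c in range(toy_alignment.length)
                   if len(column_residue_table(toy_alignment)[c]) >= 2]
        for c in present:
            assert scores.column_scores[c] == pytest.approx(1.0)
        np.testing.assert_allclose(scores.sequence_scores, 1.0)
        assert scores.alignment_score == pytest.approx(1.0)

    def test_residue_tcs_is_mean_over_column_partners(self):
        aln = Alignment(["x", "y", "z"], ["A", "A", "A"])
        pair_scores = {((0, 1), (1, 1)): 0.4, ((0, 1), (2, 1)): 0.8,
                       ((1, 1), (2, 1)): 0.1}
        assert residue_tcs(pair_scores, aln, 0, 1) == pytest.approx(0.6)

    def test_column_tcs_is_mean_over_column_pairs(self):
        aln = Alignment(["x", "y", "z"], ["A", "A", "A"])
        pair_scores = {((0, 1), (1, 1)): 0.3, ((0, 1), (2, 1)): 0.6,
                       ((1, 1), (2, 1)): 0.9}
        assert column_tcs(pair_scores, aln, 1) == pytest.approx(0.6)

    def test_singleton_residue_and_empty_column_score_zero(self):
        aln = Alignment(["x", "y"], ["AC", "A-"])
        lib = intra_column_library(aln)
        scores = compute_scores(aln, lib)
        assert scores.residue_scores[(0, 2)] == 0.0  # alone in its column
        assert scores.column_scores[1] == 0.0

    def test_gap_coordinate_rejected_for_residue_score(self):
        aln = Alignment(["x", "y"], ["A-C", "AAC"])
        with pytest.raises(TcsError):
            residue_tcs({}, aln, 0, 99)

    def test_alignment_score_is_residue_level_mean(self):
        """With unequal residue counts the residue mean is authoritative."""
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 4, 10)
        lib = random_library(rng, aln)
        scores = compute_scores(aln, lib)
        assert scores.alignment_score == pytest.approx(
            np.mean(list(scores.residue_scores.values())))

    def test_all_scores_within_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            aln = random_alignment(rng, int(rng.integers(2, 6)),
                                   int(rng.integers(2, 9)))
            lib = random_library(rng, aln)
            scores = compute_scores(aln, lib)
            vals = (list(scores.residue_scores.values())
                    + list(scores.column_scores)
                    + list(scores.sequence_scores)
                    + [scores.alignment_score]
                    + list(scores.pair_scores.values()))
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_sequence_reordering_permutes_scores_consistently(self):
        rng = np.random.default_rng(21)
        aln = random_alignment(rng, 5, 8)
        lib = random_library(rng, aln, 50)
        scores = compute_scores(aln, lib)
        perm = [3, 0, 4, 1, 2]
        aln_p = Alignment([aln.names[p] for p in perm],
                          [aln.rows[p] for p in perm])
        from tcscore import Library
        lib_p = Library(aln_p.names, [aln_p.ungapped(i) for i in range(5)])
        inv = {p: i for i, p in enumerate(perm)}
        for sa, pa, sb, pb, w in lib.entries():
            lib_p.add(inv[sa], pa, inv[sb], pb, w)
        scores_p = compute_scores(aln_p, lib_p)
        np.testing.assert_allclose(
            scores_p.sequence_scores,
            [scores.sequence_scores[p] for p in perm], atol=1e-12)
        np.testing.assert_allclose(scores_p.column_scores,
                                   scores.column_scores, atol=1e-12)
        assert scores_p.alignment_score == pytest.approx(
            scores.alignment_score, abs=1e-12)


class TestScale:
    @pytest.mark.parametrize("value,expected", [
        (0.0, 0), (0.05, 0), (0.1, 1), (0.39999, 3), (0.4, 4), (0.7, 7),
        (0.95, 9), (1.0, 9),
    ])
    def test_floor_mapping(self, value, expected):
        assert scale_to_0_9(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(TcsError):
            scale_to_0_9(1.2)
        with pytest.raises(TcsError):
            scale_to_0_9(-0.1)
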