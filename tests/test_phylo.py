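"""Distances, neighbor joining, bootstrap and newick output."""

import numpy as np
import pytest
from oracles import random_additive_tree

from eetcensus import synth
from eetcensus.phylo import (DistanceMatrix, Tree, bootstrap_support,
                             distance_matrix, neighbor_joining, nj_tree,
                             pairwise_identity)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 100.0

    def test_single_substitution_in_ten(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAT") == pytest.approx(90.0)

    def test_symmetric(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = "".join(rng.choice(list("ACGT"), size=180))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_end_gaps_excluded_from_denominator(self):
        # 10 aligned columns identical; overhang should not dilute identity
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTACGGGG"
                                 ) == pytest.approx(100.0)


class TestDistanceMatrix:
    def _seqs(self, *seqs):
        return [(f"t{i}", s) for i, s in enumerate(seqs)]

    def test_identical_pair_zero_under_both_models(self):
        s = "ACGT" * 25
        third = "ACGT" * 20 + "TGCA" * 5  # related but distinct
        for model in ("p", "jukes_cantor"):
            dm = distance_matrix(self._seqs(s, s, third), model)
            assert dm.d[0, 1] == pytest.approx(0.0)

    def test_jukes_cantor_closed_form_at_p_01(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90  # p = 0.1
        dm = distance_matrix(self._seqs(a, b, a), "jukes_cantor")
        assert dm.d[0, 1] == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))
        assert dm.d[0, 1] == pytest.approx(0.10732, abs=1e-5)

    def test_pairwise_deletion_of_gap_sites(self):
        a = "ACGTACGTAC"
        b = "-CGTACGTAT"  # 9 comparable sites, 1 mismatch
        dm = distance_matrix(self._seqs(a, b, a), "p")
        assert dm.d[0, 1] == pytest.approx(1 / 9)

    def test_all_gap_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="no comparable"):
            distance_matrix(self._seqs("AAAA----", "----CCCC", "ACGTACGT"))

    def test_saturation_error_names_the_pair(self):
        with pytest.raises(ValueError, match="t0.*t1"):
            distance_matrix(self._seqs("A" * 100, "C" * 100, "A" * 100),
                            "jukes_cantor")

    def test_permutation_equivariance(self, rng):
        seqs = [(f"t{i}", "".join(rng.choice(list("ACGT"), size=120)))
                for i in range(5)]
        dm = distance_matrix(seqs)
        perm = [3, 1, 4, 0, 2]
        dm2 = distance_matrix([seqs[i] for i in perm])
        for i, pi in enumerate(perm):
            for j, pj in enumerate(perm):
                assert dm2.d[i, j] == pytest.approx(dm.d[pi, pj])

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            distance_matrix(self._seqs("ACGT", "ACG", "ACGT"))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(list("ABC"),
                            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        tree = neighbor_joining(dm)
        # three-point formulas: la=(3+5-6)/2=1, lb=(3+6-5)/2=2, lc=(5+6-3)/2=4
        assert tree.newick() == "(A:1,B:2,C:4);"

    def test_four_taxon_additive_matrix_recovered(self):
        # path sums on ((A:1,B:2):1,(C:3,D:4))
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert tree.bipartitions() == {
            frozenset([frozenset("AB"), frozenset("CD")])}
        np.testing.assert_allclose(tree.path_lengths().d, d)

    @pytest.mark.parametrize("n_taxa", range(4, 11))
    def test_random_additive_matrices_reconstructed_exactly(self, n_taxa):
        rng = np.random.default_rng(1000 + n_taxa)
        for _ in range(5):
            _, labels, dist, splits = random_additive_tree(n_taxa, rng)
            n = len(labels)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = dist[frozenset([labels[i], labels[j]])]
            tree = neighbor_joining(DistanceMatrix(labels, d))
            assert tree.bipartitions() == splits
            pl = tree.path_lengths()
            order = [pl.taxa.index(l) for l in labels]
            np.testing.assert_allclose(pl.d[np.ix_(order, order)], d,
                                       atol=1e-8)

    def test_agrees_with_independent_nj_oracle(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        aln = synth.gen_msa_on_tree(
            "((A:0.1,B:0.15):0.05,(C:0.12,D:0.08):0.07,(E:0.1,F:0.1):0.03);",
            2000, 1.0, 99)
        dm = distance_matrix(aln, "p")
        mine = nj_tree(aln, "p")
        oracle = skbio_nj(SkbioDM(dm.d, ids=dm.taxa))
        oracle_splits = set()
        all_leaves = frozenset(dm.taxa)
        for node in oracle.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(all_leaves) - 2:
                oracle_splits.add(frozenset([below, all_leaves - below]))
        assert mine.bipartitions() == oracle_splits

    def test_deterministic_output(self):
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4],
                      [4, 4, 0, 2], [4, 4, 2, 0]], float)
        t1 = neighbor_joining(DistanceMatrix(list("ABCD"), d)).newick()
        t2 = neighbor_joining(DistanceMatrix(list("ABCD"), d)).newick()
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("ABC"),
                           np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(list("AB"),
                                            np.array([[0, 1], [1, 0]], float)))


class TestNewick:
    def test_round_trip_stable(self):
        rng = np.random.default_rng(31)
        _, labels, dist, _ = random_additive_tree(6, rng)
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = dist[frozenset([labels[i], labels[j]])]
        tree = neighbor_joining(DistanceMatrix(labels, d))
        text = tree.newick()
        assert Tree.from_newick(text).newick() == text

    def test_leaf_labels_exactly_once(self):
        dm = DistanceMatrix(list("ABC"),
                            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        names = neighbor_joining(dm).leaf_names()
        assert sorted(names) == ["A", "B", "C"]


class TestBootstrap:
    def test_uniform_alignment_gives_full_support(self):
        aln = synth.gen_msa_on_tree(
            "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,(E:0.2,F:0.2):0.1);",
            800, 1.0, 5)
        tree = bootstrap_support(aln, 30, seed=1)
        supports = _collect_supports(tree)
        assert supports and all(s == pytest.approx(100.0) for s in supports)

    def test_fixed_seed_is_reproducible(self):
        aln = synth.gen_msa_on_tree(
            "((A:0.3,B:0.3):0.02,(C:0.3,D:0.3):0.02,(E:0.3,F:0.3):0.02);",
            300, 1.0, 8)
        t1 = bootstrap_support(aln, 25, seed=42).newick()
        t2 = bootstrap_support(aln, 25, seed=42).newick()
        assert t1 == t2

    def test_modal_bipartitions_match_generating_tree(self):
        generating = "((A:0.08,B:0.1):0.05,(C:0.09,D:0.1):0.05,(E:0.1,F:0.08):0.04);"
        aln = synth.gen_msa_on_tree(generating, 5000, 1.0, 13)
        tree = bootstrap_support(aln, 40, seed=3)
        truth_splits = Tree.from_newick(generating).bipartitions()
        assert tree.bipartitions() == truth_splits
        assert all(s > 60 for s in _collect_supports(tree))

    def test_replicate_count_validated(self):
        aln = [("A", "ACGT"), ("B", "ACGT"), ("C", "ACGA")]
        with pytest.raises(ValueError):
            bootstrap_support(aln, 0, seed=1)


def _collect_supports(tree):
    out = []

    def walk(node):
        if node.support is not None:
            out.append(node.support)
        for c, _ in node.children:
            walk(c)

    walk(tree.root)
    return out
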