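"""Neighbour joining: distances, consistency on additive data, bootstrap."""

import numpy as np
import pytest

from anitax.phylo import (bipartitions, bootstrap_support, nj_tree,
                          p_distance_matrix, random_tree, tree_distance_matrix)
from anitax.seqio import SymMatrix


from conftest import perfect_alignment


class TestPDistance:
    def test_identical_pair_zero(self):
        d = p_distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGA"})
        assert d.value("a", "b") == 0.0

    def test_printed_difference_count(self, profile_pair_6087):
        anc, make = profile_pair_6087
        other = make(1108)
        d = p_distance_matrix({"anc": anc.concat, "div": other.concat,
                               "x": anc.concat})
        assert round(d.value("anc", "div"), 4) == round(1108 / 6087, 4) == 0.1820

    def test_complement_of_similarity(self, profile_pair_6087):
        from anitax.mlsa import pairwise_similarity

        anc, make = profile_pair_6087
        other = make(500)
        sim = pairwise_similarity(anc, other).similarity_pct
        d = p_distance_matrix({"a": anc.concat, "b": other.concat, "c": anc.concat})
        assert d.value("a", "b") == pytest.approx(1 - sim / 100, abs=1e-12)

    def test_zero_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix({"a": "NNNN", "b": "ACGT", "c": "ACGT"})

    def test_jukes_cantor_exceeds_p(self):
        d_p = p_distance_matrix({"a": "AAAAAAAAAA", "b": "AAAAAACCCC", "c": "AAAAAAAAAA"})
        d_jc = p_distance_matrix({"a": "AAAAAAAAAA", "b": "AAAAAACCCC", "c": "AAAAAAAAAA"},
                                 jukes_cantor=True)
        assert d_jc.value("a", "b") > d_p.value("a", "b")


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = SymMatrix(["a", "b", "c"],
                      np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float),
                      kind="distance")
        t = nj_tree(d)
        lengths = {n.name: n.length for n in t.tree.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)

    def test_additive_matrix_recovers_tree_and_lengths(self):
        true = random_tree(list("abcde"), seed=17)
        d = tree_distance_matrix(true)
        est = nj_tree(d)
        assert bipartitions(est.tree) == bipartitions(true)
        np.testing.assert_allclose(tree_distance_matrix(est.tree)
                                   .submatrix(d.labels).values,
                                   d.values, atol=1e-9)

    def test_equidistant_taxa_tie_flagged(self):
        vals = np.ones((4, 4)) - np.eye(4)
        d = SymMatrix(list("abcd"), vals, kind="distance")
        t = nj_tree(d)
        assert t.tie_joins >= 1
        assert t.clamped_edges >= 0

    def test_agrees_with_reference_nj_topology(self):
        """Cross-check against the scikit-bio NJ implementation."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(23)
        true = random_tree(list("abcdefg"), seed=29)
        d = tree_distance_matrix(true)
        noisy = d.values + rng.uniform(0, 0.01, d.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        mine = nj_tree(SymMatrix(d.labels, noisy, kind="distance"))
        ref = sk_nj(SkDM(noisy, d.labels))
        assert bipartitions(mine.tree) == bipartitions(ref)

    def test_negative_branch_lengths_clamped(self):
        # strongly non-additive matrix forces a negative NJ estimate
        vals = np.array([[0, 1, 10, 10], [1, 0, 1, 10], [10, 1, 0, 1], [10, 10, 1, 0]],
                        dtype=float)
        t = nj_tree(SymMatrix(list("abcd"), vals, kind="distance"))
        for node in t.tree.traverse(include_self=False):
            assert node.length >= 0

    def test_non_finite_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        m = SymMatrix.identity(list("abc"), kind="distance")
        m.values[0, 1] = m.values[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            nj_tree(m)


class TestBootstrap:
    def test_perfect_signal_all_supports_100(self):
        tree = random_tree(list("abcdef"), seed=31)
        aln = perfect_alignment(tree)
        result = bootstrap_support(aln, n_reps=100, seed=1)
        assert result.supports
        assert all(v == 100.0 for v in result.supports.values())
        assert bipartitions(result.tree) == bipartitions(tree)

    def test_zero_replicates_plain_tree(self):
        tree = random_tree(list("abcde"), seed=37)
        aln = perfect_alignment(tree)
        result = bootstrap_support(aln, n_reps=0)
        assert result.supports is None

    def test_seeded_determinism(self):
        tree = random_tree(list("abcdef"), seed=41)
        aln = perfect_alignment(tree, per_edge=8, per_leaf=2)
        r1 = bootstrap_support(aln, n_reps=50, seed=7)
        r2 = bootstrap_support(aln, n_reps=50, seed=7)
        assert r1.supports == r2.supports
        assert r1.newick() == r2.newick()

    def test_supports_invariant_to_leaf_order(self):
        tree = random_tree(list("abcdef"), seed=43)
        aln = perfect_alignment(tree)
        shuffled = {k: aln[k] for k in reversed(sorted(aln))}
        r1 = bootstrap_support(aln, n_reps=50, seed=3)
        r2 = bootstrap_support(shuffled, n_reps=50, seed=3)
        assert r1.supports == r2.supports

    def test_newick_carries_support_labels(self):
        tree = random_tree(list("abcdef"), seed=47)
        result = bootstrap_support(perfect_alignment(tree), n_reps=20, seed=5)
        assert "100" in result.newick()
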