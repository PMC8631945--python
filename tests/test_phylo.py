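"""Tree covariance, Blomberg's K / K_mult, permutation test and pPCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gnathomech import (Phylogeny, PhylogeneticPCA, blomberg_k, k_mult,
                        permutation_test, phylo_covariance, phylogenetic_pca,
                        read_newick, simulate_bm_traits, simulate_tree)
from gnathomech.functional import FunctionalPCA, fix_component_signs


class TestCovariance:
    def test_three_taxon_example(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        C = phylo_covariance(tree)
        idx = {lab: i for i, lab in enumerate(tree.tip_labels)}
        expected = np.zeros((3, 3))
        expected[idx["A"], idx["A"]] = 2
        expected[idx["B"], idx["B"]] = 2
        expected[idx["C"], idx["C"]] = 2
        expected[idx["A"], idx["B"]] = expected[idx["B"], idx["A"]] = 1
        np.testing.assert_allclose(C, expected)

    def test_star_tree_is_identity(self, star3_tree):
        np.testing.assert_allclose(phylo_covariance(star3_tree), np.eye(3))

    def test_ultrametric_constant_diagonal(self, balanced4_tree):
        C = phylo_covariance(balanced4_tree)
        np.testing.assert_allclose(np.diag(C), 2.0)

    def test_duplicate_tip_labels_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            Phylogeny.from_newick("((A:1,A:1):1,C:2);")

    def test_negative_branch_length_error(self):
        tree = Phylogeny.from_newick("((A:1,B:-0.5):1,C:2);")
        with pytest.raises(ValueError, match="negative"):
            tree.covariance()

    def test_matches_patristic_distance_identity(self):
        """Independent oracle: MRCA depth = (depth_i + depth_j - d_ij)/2
        with d the patristic distance from dendropy."""
        for seed in (1, 2, 3):
            tree = simulate_tree(10, seed=seed)
            C = tree.covariance()
            pdm = tree.tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.tree.taxon_namespace}
            labels = tree.tip_labels
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i >= j:
                        continue
                    d = pdm.distance(taxa[a], taxa[b])
                    np.testing.assert_allclose(
                        C[i, j], (C[i, i] + C[j, j] - d) / 2.0, atol=1e-10)

    def test_read_newick_file(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        assert read_newick(path).n_tips == 3


class TestAttachTip:
    def test_graft_on_tip_edge(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        out = tree.attach_tip("F", below="A", stem_fraction=0.5)
        assert out.n_tips == 4
        C = out.covariance()
        i = {lab: k for k, lab in enumerate(out.tip_labels)}
        # split point at depth 1.5; F reaches the deepest tip depth (2.0)
        np.testing.assert_allclose(C[i["F"], i["A"]], 1.5)
        np.testing.assert_allclose(C[i["F"], i["F"]], 2.0)
        assert tree.n_tips == 3  # original untouched

    def test_graft_on_mrca_edge(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        out = tree.attach_tip("F", below="A|B", stem_fraction=0.5)
        C = out.covariance()
        i = {lab: k for k, lab in enumerate(out.tip_labels)}
        np.testing.assert_allclose(C[i["F"], i["A"]], 0.5)
        np.testing.assert_allclose(C[i["F"], i["C"]], 0.0)

    def test_duplicate_label_rejected(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="already"):
            tree.attach_tip("A", below="B")


class TestBlombergK:
    def test_star_tree_is_exactly_one(self):
        tree = Phylogeny.from_newick("(A:1.5,B:1.5,C:1.5,D:1.5);")
        trait = np.array([0.3, -1.2, 2.5, 0.7])
        assert blomberg_k(trait, tree) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-10, 10).filter(lambda a: abs(a) > 1e-3),
           st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        trait = np.array([1.0, 2.0, 7.0, 9.0])
        k0 = blomberg_k(trait, tree)
        assert blomberg_k(a * trait + b, tree) == pytest.approx(k0, rel=1e-9)

    def test_matches_matrix_oracle(self, balanced4_tree):
        """Direct linear-algebra oracle on the 4-taxon fixture with a
        hand-built covariance matrix."""
        order = balanced4_tree.tip_labels
        trait_by_label = {"A": 1.0, "B": 2.0, "C": 7.0, "D": 9.0}
        x = np.array([trait_by_label[l] for l in order])
        C = np.array([[2.0, 1.0, 0.0, 0.0], [1.0, 2.0, 0.0, 0.0],
                      [0.0, 0.0, 2.0, 1.0], [0.0, 0.0, 1.0, 2.0]])
        # reorder the hand matrix to the tree's tip order
        pos = {"A": 0, "B": 1, "C": 2, "D": 3}
        P = np.zeros((4, 4))
        for k, lab in enumerate(order):
            P[k, pos[lab]] = 1.0
        C = P @ C @ P.T
        n = 4
        Cinv = np.linalg.inv(C)
        ones = np.ones(n)
        a = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
        mse0 = (x - a) @ (x - a) / (n - 1)
        mse = (x - a) @ Cinv @ (x - a) / (n - 1)
        expected_ratio = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
        oracle = (mse0 / mse) / expected_ratio
        assert blomberg_k(x, balanced4_tree) == pytest.approx(oracle, rel=1e-12)

    def test_constant_trait_errors(self, balanced4_tree):
        with pytest.raises(ValueError, match="undefined"):
            blomberg_k(np.ones(4), balanced4_tree)


class TestKMult:
    def test_reduces_to_univariate(self, rng):
        tree = simulate_tree(8, seed=5)
        x = simulate_bm_traits(tree, 1, seed=6)
        assert k_mult(x, tree) == pytest.approx(
            blomberg_k(x[:, 0], tree), abs=1e-12)

    def test_star_tree_is_one(self):
        tree = Phylogeny.from_newick("(A:2,B:2,C:2,D:2,E:2);")
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (5, 3))
        assert k_mult(X, tree) == pytest.approx(1.0, abs=1e-12)

    def test_matches_matrix_oracle(self):
        tree = Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (5, 3))
        C = tree.covariance()
        n = 5
        Cinv = np.linalg.inv(C)
        ones = np.ones(n)
        denom = ones @ Cinv @ ones
        a = (ones @ Cinv @ X) / denom
        R = X - a
        num = np.sum(R * R)
        den = np.sum(R * (Cinv @ R))
        expected_ratio = (np.trace(C) - n / denom) / (n - 1)
        oracle = (num / den) / expected_ratio
        assert k_mult(X, tree) == pytest.approx(oracle, rel=1e-12)


class TestPermutationTest:
    def test_p_value_invariant_holds(self):
        tree = simulate_tree(12, seed=9)
        x = simulate_bm_traits(tree, 1, seed=10)[:, 0]
        res = permutation_test("K", x, tree, n_permutations=199, seed=4)
        recomputed = (1 + np.count_nonzero(res.permutation_values
                                           >= res.observed)) / 200
        assert res.p_value == pytest.approx(recomputed)
        assert res.p_value >= 1.0 / 200

    def test_seeded_reproducibility(self):
        tree = simulate_tree(10, seed=2)
        X = simulate_bm_traits(tree, 3, seed=3)
        r1 = permutation_test("K_mult", X, tree, n_permutations=99, seed=11)
        r2 = permutation_test("K_mult", X, tree, n_permutations=99, seed=11)
        np.testing.assert_array_equal(r1.permutation_values,
                                      r2.permutation_values)
        assert r1.p_value == r2.p_value

    def test_strong_clade_signal_reaches_p_floor(self):
        """A trait that perfectly separates two deep clades beats (almost)
        every tip shuffle; the add-one p-value approaches its floor
        1/(n_permutations + 1)."""
        tree = Phylogeny.from_newick(
            "((A:1,(B:0.5,C:0.5):0.5):3,((D:0.5,E:0.5):0.5,F:1):3);")
        clade1 = {"A", "B", "C"}
        x = np.array([10.0 + 0.01 * i if lab in clade1 else 0.01 * i
                      for i, lab in enumerate(tree.tip_labels)])
        res = permutation_test("K", x, tree, n_permutations=999, seed=21)
        assert res.p_value <= 0.05
        assert res.p_value >= 1.0 / 1000

    def test_requires_seed(self, balanced4_tree):
        with pytest.raises(ValueError, match="seed"):
            permutation_test("K", np.array([1.0, 2, 3, 4]), balanced4_tree,
                             n_permutations=99, seed=None)


class TestPhylogeneticPCA:
    def test_star_tree_equals_ordinary_pca(self):
        tree = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(13)
        X = rng.normal(0, 1, (6, 3))
        res = phylogenetic_pca(X, tree)
        ord_scores = FunctionalPCA().fit_transform(X)
        np.testing.assert_allclose(res.scores, ord_scores, atol=1e-8)

    def test_eigenvalue_sum_equals_trace(self):
        tree = simulate_tree(9, seed=17)
        X = simulate_bm_traits(tree, 4, seed=18)
        res = phylogenetic_pca(X, tree)
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(res.evolutionary_covariance), abs=1e-10)
        assert res.variance_explained.sum() == pytest.approx(100.0)

    def test_matches_gls_oracle(self):
        """Step-by-step GLS oracle on a 5-taxon fixture, to 1e-10."""
        tree = Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
        rng = np.random.default_rng(19)
        X = rng.normal(0, 1, (5, 3))
        C = tree.covariance()
        Cinv = np.linalg.inv(C)
        ones = np.ones(5)
        a = (ones @ Cinv @ X) / (ones @ Cinv @ ones)
        R = (X - a).T @ Cinv @ (X - a) / 4.0
        evals, evecs = np.linalg.eigh(R)
        idx = np.argsort(evals)[::-1]
        evals, evecs = evals[idx], evecs[:, idx]
        scores = (X - a) @ evecs
        loadings, scores = fix_component_signs(evecs.T, scores)
        res = phylogenetic_pca(X, tree)
        np.testing.assert_allclose(res.phylogenetic_mean, a, atol=1e-10)
        np.testing.assert_allclose(res.eigenvalues, evals, atol=1e-10)
        np.testing.assert_allclose(res.scores, scores, atol=1e-10)
        np.testing.assert_allclose(res.loadings, loadings, atol=1e-10)

    def test_warns_when_underdetermined(self, balanced4_tree):
        rng = np.random.default_rng(23)
        with pytest.warns(UserWarning, match="descriptors"):
            PhylogeneticPCA(tree=balanced4_tree).fit(rng.normal(0, 1, (4, 5)))

    def test_transform_matches_fit_scores(self):
        tree = simulate_tree(8, seed=29)
        X = simulate_bm_traits(tree, 3, seed=30)
        est = PhylogeneticPCA(tree=tree).fit(X)
        np.testing.assert_allclose(est.transform(X), est.scores_, atol=1e-10)
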