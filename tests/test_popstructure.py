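"""F_ST estimator, ASD, NJ trees, PCA and K-means behavior."""

import numpy as np
import pytest

import popkit as pk

from conftest import make_panel


def flip_alleles(panel, snp_mask):
    d = panel.dosages.copy()
    d[:, snp_mask] = 2 - d[:, snp_mask]
    return pk.GenotypePanel(list(panel.sample_ids), dict(panel.pop_of),
                            list(panel.snps), d)


class TestPairwiseFst:
    def test_fixed_difference_is_near_one(self):
        d = np.vstack([np.full((50, 1), 2.0), np.zeros((50, 1))])
        panel = make_panel(d, ["A"] * 50 + ["B"] * 50)
        fst, n = pk.pairwise_fst(panel, "A", "B")
        assert n == 1
        assert fst >= 0.97

    def test_identical_sample_sets_give_zero(self):
        rng = np.random.default_rng(0)
        block = rng.binomial(2, rng.uniform(0.1, 0.9, 1000), (30, 1000)).astype(float)
        panel = make_panel(np.vstack([block, block]), ["A"] * 30 + ["B"] * 30)
        fst, _ = pk.pairwise_fst(panel, "A", "B")
        assert fst <= 0.005

    def test_balding_nichols_recovery(self):
        # Monte-Carlo oracle for two branches of F each: WC ratio-of-sums
        # estimate centers on F (oracle mean 0.0100 at F = 0.01).
        F = 0.005
        panel = pk.simulate_divergence(pk.DivergenceModel(
            pop_specs=[("A", F, 100), ("B", F, 100)], n_snps=20_000, seed=42))
        fst, _ = pk.pairwise_fst(panel, "A", "B")
        assert fst == pytest.approx(F, rel=0.2)

    def test_symmetry_and_allele_flip_invariance(self, two_pop_panel):
        f_ab, _ = pk.pairwise_fst(two_pop_panel, "P1", "P2")
        f_ba, _ = pk.pairwise_fst(two_pop_panel, "P2", "P1")
        assert f_ab == pytest.approx(f_ba)
        rng = np.random.default_rng(1)
        flipped = flip_alleles(two_pop_panel,
                               rng.random(two_pop_panel.n_snps) < 0.5)
        f_flip, _ = pk.pairwise_fst(flipped, "P1", "P2")
        assert f_flip == pytest.approx(f_ab)

    def test_monotone_in_drift(self):
        ests = []
        for F in (0.002, 0.01, 0.05):
            panel = pk.simulate_divergence(pk.DivergenceModel(
                pop_specs=[("A", F, 60), ("B", F, 60)], n_snps=8_000, seed=9))
            ests.append(pk.pairwise_fst(panel, "A", "B")[0])
        assert ests[0] < ests[1] < ests[2]

    def test_monomorphic_only_errors(self):
        panel = make_panel(np.zeros((8, 3)), ["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError, match="no usable"):
            pk.pairwise_fst(panel, "A", "B")


class TestFstMatrix:
    def test_identical_populations_near_zero(self):
        # three populations drawn from the same frequencies (no drift)
        panel = pk.simulate_divergence(pk.DivergenceModel(
            pop_specs=[("A", 0.0, 20), ("B", 0.0, 20), ("C", 0.0, 20)],
            n_snps=3_000, seed=3))
        m = pk.fst_matrix(panel)
        off = m.values.to_numpy()[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 0.005).all()
        assert np.allclose(np.diag(m.values), 0)

    def test_star_tree_ordering(self):
        panel = pk.simulate_divergence(pk.DivergenceModel(
            pop_specs=[("REF", 0.0, 40), ("D1", 0.005, 40),
                       ("D2", 0.02, 40), ("D3", 0.08, 40)],
            n_snps=5_000, seed=10))
        m = pk.fst_matrix(panel).values
        assert m.loc["REF", "D1"] < m.loc["REF", "D2"] < m.loc["REF", "D3"]

    def test_two_population_consistency(self, two_pop_panel):
        m = pk.fst_matrix(two_pop_panel)
        f, _ = pk.pairwise_fst(two_pop_panel, "P1", "P2")
        assert m.values.loc["P1", "P2"] == pytest.approx(f)
        assert m.values.loc["P2", "P1"] == pytest.approx(f)


class TestAsd:
    def test_hand_case(self):
        panel = make_panel([[0, 1, 2, 2], [2, 1, 0, 2]], ["A", "B"])
        d = pk.asd_matrix(panel).values
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_identical_and_maximal(self):
        panel = make_panel([[1, 2, 0], [1, 2, 0], [0, 0, 0], [2, 2, 2]],
                           ["A"] * 4)
        d = pk.asd_matrix(panel).values.to_numpy()
        assert d[0, 1] == 0
        assert d[2, 3] == 1

    def test_missing_excluded_pairwise(self):
        panel = make_panel([[0, 1, np.nan], [2, 1, 2]], ["A", "B"])
        d = pk.asd_matrix(panel).values
        assert d.iloc[0, 1] == pytest.approx(0.5)  # only first two SNPs

    def test_no_shared_snps_errors(self):
        panel = make_panel([[1, np.nan], [np.nan, 1]], ["A", "B"])
        with pytest.raises(ValueError, match="no shared"):
            pk.asd_matrix(panel)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, (12, 300)).astype(float)
        m = pk.asd_matrix(make_panel(d, ["A"] * 12)).values.to_numpy()
        n = m.shape[0]
        for i in range(n):
            for j in range(n):
                assert (m[i, :] <= m[i, j] + m[j, :] + 1e-12).all()


def _dist(ids, values):
    import pandas as pd
    return pk.DistanceMatrix(ids=ids, values=pd.DataFrame(
        values, index=ids, columns=ids, dtype=float))


class TestNjTree:
    ADDITIVE = np.array([  # from ((A:1,B:2):1,(C:3,D:4))
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0]], float)

    def test_additive_matrix_recovered_exactly(self):
        import skbio
        nwk = pk.nj_tree(_dist(list("ABCD"), self.ADDITIVE))
        tree = skbio.TreeNode.read([nwk])
        # patristic distances reproduce the input exactly (additivity)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                        self.ADDITIVE[i, j])
        # AB|CD split present
        tips = {frozenset(t.name for t in cl.tips())
                for cl in tree.non_tips(include_self=False)}
        assert frozenset("AB") in tips or frozenset("CD") in tips

    def test_three_taxa_three_point_formula(self):
        nwk = pk.nj_tree(_dist(list("ABC"), np.array(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)))
        import skbio
        tree = skbio.TreeNode.read([nwk])
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("B").length == pytest.approx(2.0)
        assert tree.find("C").length == pytest.approx(3.0)

    def test_matches_reference_nj_topology(self):
        import skbio
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 3))
        names = [f"t{i}" for i in range(7)]
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = skbio.TreeNode.read([pk.nj_tree(_dist(names, D))])
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=names))
        def splits(tree):
            all_tips = frozenset(names)
            out = set()
            for cl in tree.non_tips(include_self=False):
                s = frozenset(t.name for t in cl.tips())
                out.add(min(s, all_tips - s, key=sorted))
            return out
        assert splits(ours) == splits(ref)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            pk.nj_tree(_dist(list("ABC"), np.array(
                [[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)))

    def test_population_monophyly_under_drift(self):
        import skbio
        good = 0
        for seed in range(20):
            panel = pk.simulate_divergence(pk.DivergenceModel(
                pop_specs=[("A", 0.05, 8), ("B", 0.05, 8)],
                n_snps=1_000, seed=200 + seed))
            nwk = pk.nj_tree(pk.asd_matrix(panel))
            tree = skbio.TreeNode.read([nwk]).root_at_midpoint()
            children = tree.children
            def pop_of(name):  # skbio renders unquoted "_" as " "
                return name.replace(" ", "_").split("_")[0]
            sets = [frozenset(pop_of(t.name) for t in ch.tips())
                    if not ch.is_tip() else frozenset([pop_of(ch.name)])
                    for ch in children]
            if all(len(s) == 1 for s in sets):
                good += 1
        assert good >= 19  # >= 95% of seeds


class TestPca:
    def test_separates_drifted_populations(self):
        panel = pk.simulate_divergence(pk.DivergenceModel(
            pop_specs=[("A", 0.05, 40), ("B", 0.05, 40)],
            n_snps=3_000, seed=21))
        res = pk.pca(panel)
        pc1 = res.coordinates[:, 0]
        a, b = pc1[:40], pc1[40:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) \
            or max(a.max(), b.max()) < min(a.min(), b.min()) \
            or (a.max() < b.min()) or (b.max() < a.min())

    def test_variance_fraction_conventions(self, two_pop_panel):
        res = pk.pca(two_pop_panel)
        assert res.var_frac_top10[:10].sum() == pytest.approx(1.0)
        assert res.var_frac_total.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(
            res.var_frac_top10[:10],
            res.eigenvalues[:10] / res.eigenvalues[:10].sum())
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert (res.eigenvalues >= 0).all()

    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(22)
        d = rng.binomial(2, 0.4, (10, 500)).astype(float)
        d[5] = d[0]
        res = pk.pca(make_panel(d, ["P"] * 10), n_components=3)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[5],
                                   atol=1e-9)

    def test_snp_order_permutation_invariance(self, two_pop_panel):
        res1 = pk.pca(two_pop_panel, n_components=4)
        # reverse SNP order (still valid coordinate sort? use new positions)
        d = two_pop_panel.dosages[:, ::-1].copy()
        panel2 = make_panel(d, [two_pop_panel.pop_of[s]
                                for s in two_pop_panel.sample_ids])
        res2 = pk.pca(panel2, n_components=4)
        for k in range(4):
            dot = np.dot(res1.coordinates[:, k], res2.coordinates[:, k])
            sign = 1.0 if dot >= 0 else -1.0
            np.testing.assert_allclose(res1.coordinates[:, k],
                                       sign * res2.coordinates[:, k],
                                       atol=1e-6)

    def test_monomorphic_only_errors(self):
        panel = make_panel(np.ones((4, 5)), ["P"] * 4)
        with pytest.raises(ValueError):
            pk.pca(panel)


class TestKmeans:
    def test_two_blobs_perfect_fractions(self):
        panel = pk.simulate_divergence(pk.DivergenceModel(
            pop_specs=[("A", 0.1, 30), ("B", 0.1, 30)], n_snps=2_000, seed=31))
        res = pk.kmeans_on_pcs(pk.pca(panel), panel, K=2, seed=0)
        fr = res.fractions
        assert set(fr.index) == {"A", "B"}
        np.testing.assert_allclose(fr.sum(axis=1), 1.0)
        assert sorted(fr.loc["A"].to_numpy()) == [0.0, 1.0]
        assert fr.loc["A"].idxmax() != fr.loc["B"].idxmax()

    def test_single_cluster(self, two_pop_panel):
        res = pk.kmeans_on_pcs(pk.pca(two_pop_panel), two_pop_panel, K=1)
        assert (res.assignments == 0).all()

    def test_close_populations_share_cluster(self):
        panel = pk.simulate_divergence(pk.DivergenceModel(
            pop_specs=[("N1", 0.004, 30), ("N2", 0.004, 30), ("FAR", 0.15, 30)],
            n_snps=3_000, seed=32))
        res = pk.kmeans_on_pcs(pk.pca(panel), panel, K=2, seed=0)
        assert res.fractions.loc["N1"].idxmax() == res.fractions.loc["N2"].idxmax()
        assert res.fractions.loc["FAR"].idxmax() != res.fractions.loc["N1"].idxmax()

    def test_too_many_clusters_rejected(self, two_pop_panel):
        with pytest.raises(ValueError):
            pk.kmeans_on_pcs(pk.pca(two_pop_panel), two_pop_panel,
                             K=two_pop_panel.n_samples + 1)
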