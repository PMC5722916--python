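"""Network construction, TOM, clustering, module statistics.

Hand-computable cases come first; seeded instances are checked against
naive oracles (triple-loop TOM, pairwise average-linkage, eigendecomposition).
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as student_t

import coexkit as ck
from coexkit.coexpression import (
    CoexpressionNetwork,
    NetworkConfig,
    compute_eigengenes,
    cluster_genes,
    cut_tree,
)
from coexkit.io import ValidationError


def _exact_cor_pair(rho: float, n: int = 20) -> pd.DataFrame:
    """Two profiles with exactly the requested sample correlation."""
    rng = np.random.default_rng(42)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = rng.normal(size=n)
    z = z - z.mean() - x * (x @ (z - z.mean())) / (x @ x)
    z = z / z.std()
    y = rho * x + np.sqrt(1 - rho ** 2) * z
    return pd.DataFrame([x, y], index=["gx", "gy"])


class TestSignedHybridAdjacency:
    def test_perfect_correlation_gives_one(self):
        df = _exact_cor_pair(1.0)
        adj = ck.signed_hybrid_adjacency(df, beta=7)
        assert adj.loc["gx", "gy"] == pytest.approx(1.0)

    def test_anticorrelation_zeroed(self):
        df = _exact_cor_pair(-1.0)
        adj = ck.signed_hybrid_adjacency(df, beta=7)
        assert adj.loc["gx", "gy"] == 0.0

    def test_power_law_value(self):
        adj = ck.signed_hybrid_adjacency(_exact_cor_pair(0.9), beta=16)
        assert adj.loc["gx", "gy"] == pytest.approx(0.9 ** 16, rel=1e-9)

    def test_zero_variance_gene_listed(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            ck.signed_hybrid_adjacency(df, beta=2)

    def test_symmetric_zero_diagonal_range(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 10)))
        adj = ck.signed_hybrid_adjacency(df, beta=6).to_numpy()
        assert np.allclose(adj, adj.T)
        assert np.allclose(np.diag(adj), 0.0)
        assert adj.min() >= 0.0 and adj.max() <= 1.0


class TestScaleFreeFit:
    def test_power_law_degrees_fit_well(self):
        # rank-inverse connectivity: log p vs log k is close to collinear
        n = 200
        w = 1.0 / np.arange(1, n + 1)
        A = np.outer(w, w)
        np.fill_diagonal(A, 0.0)
        r2, slope = ck.scale_free_fit(pd.DataFrame(A))
        assert r2 > 0.9
        assert slope < 0

    def test_erdos_renyi_fits_poorly(self):
        # binomial degree distributions are not scale-free
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            A = (rng.random((300, 300)) < 0.1).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            r2, slope = ck.scale_free_fit(pd.DataFrame(A))
            r2s.append(r2)
        assert np.mean(r2s) < 0.5

    def test_equal_connectivities_rejected(self):
        A = np.ones((20, 20)) - np.eye(20)
        with pytest.raises(ValidationError):
            ck.scale_free_fit(pd.DataFrame(A))


class TestPickSoftThreshold:
    def test_zero_target_picks_smallest_negative_slope_power(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 12)))
        res = ck.pick_soft_threshold(df, candidate_powers=(2, 4, 6), target_r2=1e-9)
        ok = res.table[(res.table.slope < 0)]
        assert res.power == int(ok.iloc[0].power)

    def test_mean_connectivity_decreases_with_power(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 10)))
        res = ck.pick_soft_threshold(df, candidate_powers=(1, 2, 4, 8, 16))
        mean_k = res.table["mean_k"].to_numpy()
        assert np.all(np.diff(mean_k) <= 1e-12)

    def test_default_generator_reaches_scale_free_target(self):
        """On default synthetic data the chosen power gives R^2 >= 0.9 with
        a decaying degree distribution."""
        cfg = ck.SimulationConfig(seed=11)
        counts, ann, traits, _ = ck.simulate_expression(cfg)
        tpm = ck.compute_tpm(counts, ann)
        logtpm = ck.log_transform(tpm)
        quart = ck.select_top_quartile_variance(
            logtpm, ck.filter_expressed(tpm).selected_gene_ids)
        res = ck.pick_soft_threshold(logtpm.values.loc[list(quart.selected_gene_ids)])
        assert res.reached_target
        row = res.table[res.table.power == res.power].iloc[0]
        assert row.r2 >= 0.9
        assert row.slope < 0


class TestTopologicalOverlap:
    def test_complete_unit_graph(self):
        A = np.ones((4, 4)) - np.eye(4)
        tom = ck.topological_overlap(pd.DataFrame(A)).to_numpy()
        # l = 2, k = 3 -> (2 + 1) / (3 + 1 - 1) = 1
        assert np.allclose(tom, 1.0)

    def test_isolated_pair(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        tom = ck.topological_overlap(pd.DataFrame(A))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_empty_adjacency(self):
        tom = ck.topological_overlap(pd.DataFrame(np.zeros((5, 5)))).to_numpy()
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        A = rng.uniform(0, 1, size=(12, 12))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tom = ck.topological_overlap(pd.DataFrame(A)).to_numpy()
        n = len(A)
        k = A.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                expect = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert tom[i, j] == pytest.approx(expect, rel=1e-12)

    def test_range_and_symmetry(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 8)))
        tom = ck.topological_overlap(ck.signed_hybrid_adjacency(df, 6)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


def _naive_average_linkage(d: np.ndarray):
    """Textbook pairwise average-linkage; returns the cophenetic matrix."""
    n = len(d)
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        new_dist = {}
        for (x, y), v in dist.items():
            if a in (x, y) or b in (x, y):
                continue
            new_dist[(x, y)] = v
        for c, members in clusters.items():
            v = np.mean([d[i, j] for i in merged for j in members])
            new_dist[tuple(sorted((c, next_id)))] = v
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    return coph


class TestClusterGenes:
    def test_isolated_duplicates_merge_at_zero(self, rng):
        x = rng.normal(size=10)
        df = pd.DataFrame([x, x], index=["g0", "g1"])
        tom = ck.topological_overlap(ck.signed_hybrid_adjacency(df, 4))
        Z, order = cluster_genes(tom)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_duplicates_merge_first(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 10)),
                          index=[f"g{i}" for i in range(6)])
        df.loc["g1"] = df.loc["g0"]
        tom = ck.topological_overlap(ck.signed_hybrid_adjacency(df, 4))
        Z, order = cluster_genes(tom)
        merged = {order[int(Z[0, 0])], order[int(Z[0, 1])]}
        assert merged == {"g0", "g1"}
        # duplicates share every neighbor, so theirs is the smallest dissimilarity
        d = 1.0 - tom.to_numpy()
        iu = np.triu_indices_from(d, 1)
        assert Z[0, 2] == pytest.approx(d[iu].min(), abs=1e-12)

    def test_block_diagonal_blocks_join_last(self):
        tom = np.full((8, 8), 0.05)
        tom[:4, :4] = 0.9
        tom[4:, 4:] = 0.9
        np.fill_diagonal(tom, 1.0)
        Z, order = cluster_genes(pd.DataFrame(tom, index=[f"g{i}" for i in range(8)],
                                              columns=[f"g{i}" for i in range(8)]))
        # the final merge joins the two blocks (sizes 4 and 4)
        assert Z[-1, 3] == 8
        n = 8

        def cluster_size(idx):
            return 1 if idx < n else int(Z[int(idx) - n, 3])

        assert sorted((cluster_size(Z[-1, 0]), cluster_size(Z[-1, 1]))) == [4, 4]

    def test_cophenetic_matches_naive_oracle(self, rng):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform
        d = rng.uniform(0.1, 1.0, size=(8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tom = pd.DataFrame(1.0 - d, index=[f"g{i}" for i in range(8)],
                           columns=[f"g{i}" for i in range(8)])
        Z, order = cluster_genes(tom)
        coph = squareform(cophenet(Z))
        ref = _naive_average_linkage(d)
        assert np.allclose(coph, ref, atol=1e-10)


class TestCutTree:
    def _block_tom(self, sizes, hi=0.9, lo=0.02):
        n = sum(sizes)
        tom = np.full((n, n), lo)
        start = 0
        for s in sizes:
            tom[start:start + s, start:start + s] = hi
            start += s
        np.fill_diagonal(tom, 1.0)
        genes = [f"g{i:03d}" for i in range(n)]
        return pd.DataFrame(tom, index=genes, columns=genes)

    def test_two_planted_blocks_recovered(self):
        tom = self._block_tom([40, 40])
        Z, order = cluster_genes(tom)
        labels = cut_tree(Z, order, min_module_size=30)
        assert set(labels) == {1, 2}
        assert (labels == 0).sum() == 0
        first = labels[[f"g{i:03d}" for i in range(40)]]
        assert first.nunique() == 1

    def test_min_size_larger_than_n_unassigns_everything(self):
        tom = self._block_tom([10, 10])
        Z, order = cluster_genes(tom)
        labels = cut_tree(Z, order, min_module_size=100)
        assert (labels == 0).all()

    def test_pure_noise_yields_at_most_one_module(self, rng):
        hits = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(r.normal(size=(50, 15)),
                              index=[f"g{i:02d}" for i in range(50)])
            tom = ck.topological_overlap(ck.signed_hybrid_adjacency(df, 6))
            Z, order = cluster_genes(tom)
            labels = cut_tree(Z, order, min_module_size=30)
            hits.append(labels.max())
        assert max(hits) <= 1


class TestModuleEigengene:
    def test_identical_member_genes(self, rng):
        x = rng.normal(size=12)
        df = pd.DataFrame([x, x, x], index=["a", "b", "c"],
                          columns=[f"s{i}" for i in range(12)])
        eig = ck.module_eigengene(df, ["a", "b", "c"])
        assert np.corrcoef(eig, x)[0, 1] == pytest.approx(1.0)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_single_gene_module(self, rng):
        x = rng.normal(size=10)
        df = pd.DataFrame([x], index=["a"], columns=[f"s{i}" for i in range(10)])
        eig = ck.module_eigengene(df, ["a"])
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(eig, z / np.linalg.norm(z), atol=1e-10)

    def test_recovers_planted_activity(self):
        cfg = ck.SimulationConfig(seed=13, n_genes=1000, n_tissue_specific=5)
        counts, ann, traits, truth = ck.simulate_expression(cfg)
        logtpm = ck.log_transform(ck.compute_tpm(counts, ann))
        eig = ck.module_eigengene(logtpm.values, truth.module_genes(1))
        activity = truth.module_activity.loc[1]
        assert abs(np.corrcoef(eig, activity)[0, 1]) >= 0.9

    def test_explains_at_least_mean_profile_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 10)),
                          index=[f"g{i:02d}" for i in range(15)])
        X = df.to_numpy()
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        eig = ck.module_eigengene(df, list(df.index)).to_numpy()
        mean_dir = X.mean(axis=0)
        mean_dir = mean_dir / np.linalg.norm(mean_dir)
        assert ((X @ eig) ** 2).sum() >= ((X @ mean_dir) ** 2).sum() - 1e-9

    def test_empty_module_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 5)), index=["a", "b", "c"])
        with pytest.raises(ValidationError):
            ck.module_eigengene(df, ["zz"])


class TestMergeModules:
    def test_same_latent_modules_merge(self, rng):
        shared = rng.normal(size=20)
        rows = {f"g{i:02d}": 0.95 * shared + 0.3 * rng.normal(size=20)
                for i in range(20)}
        df = pd.DataFrame(rows).T
        labels = pd.Series([1] * 10 + [2] * 10, index=df.index)
        merged = ck.merge_modules(df, labels)
        assert merged.nunique() == 1

    def test_independent_modules_unchanged(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        rows = {}
        for i in range(10):
            rows[f"a{i}"] = a + 0.1 * rng.normal(size=30)
        for i in range(10):
            rows[f"b{i}"] = b + 0.1 * rng.normal(size=30)
        df = pd.DataFrame(rows).T
        labels = pd.Series([1] * 10 + [2] * 10, index=df.index)
        merged = ck.merge_modules(df, labels)
        assert merged.nunique() == 2

    def test_single_module_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)])
        labels = pd.Series([1] * 5, index=df.index)
        assert ck.merge_modules(df, labels).tolist() == [1] * 5


class TestModuleMembership:
    def test_single_gene_module_kme_one(self, rng):
        x = rng.normal(size=10)
        df = pd.DataFrame([x], index=["a"], columns=[f"s{i}" for i in range(10)])
        eig = compute_eigengenes(df, pd.Series([1], index=["a"]))
        kme = ck.module_membership(df, eig)
        assert kme.loc["a", 1] == pytest.approx(1.0)

    def test_noise_gene_below_threshold(self, rng):
        cfg = ck.SimulationConfig(seed=2, n_genes=300, n_cell_types=2,
                                  replicates_per_type=(15, 15), module_sizes=(30,),
                                  activity_profiles=np.zeros((1, 2)),
                                  n_tissue_specific=0, de_fraction=0.0)
        _, _, _, truth = ck.simulate_expression(cfg)
        latent = truth.latent
        labels = truth.module_labels
        eig = compute_eigengenes(latent, labels)
        kme = ck.module_membership(latent, eig)
        noise = kme.loc[labels == 0, 1].abs()
        assert (noise < 0.75).all()

    def test_planted_members_mean_kme_near_loading(self):
        cfg = ck.SimulationConfig(seed=4, n_genes=200, n_cell_types=2,
                                  replicates_per_type=(15, 15), module_sizes=(50,),
                                  activity_profiles=np.zeros((1, 2)),
                                  n_tissue_specific=0, de_fraction=0.0)
        _, _, _, truth = ck.simulate_expression(cfg)
        labels = truth.module_labels
        eig = compute_eigengenes(truth.latent, labels)
        kme = ck.module_membership(truth.latent, eig)
        member_kme = kme.loc[labels == 1, 1]
        # loadings average sqrt(0.81) = 0.9 by construction
        assert member_kme.mean() == pytest.approx(0.9, abs=0.05)

    def test_overlapping_membership_allowed(self, rng):
        shared = rng.normal(size=20)
        rows = {f"g{i}": shared + 0.05 * rng.normal(size=20) for i in range(6)}
        df = pd.DataFrame(rows).T
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=df.index)
        eig = compute_eigengenes(df, labels)
        sets = ck.assign_by_kme(ck.module_membership(df, eig))
        assert sets[1] & sets[2]  # genes may belong to multiple modules


class TestModuleTraitCorrelation:
    def _traits(self, n_a, n_b):
        ind = pd.DataFrame(
            [[1, 0]] * n_a + [[0, 1]] * n_b,
            index=[f"s{i}" for i in range(n_a + n_b)], columns=["A", "B"])
        return ck.TraitDesign(ind)

    def test_indicator_eigengene_perfect_correlation(self):
        traits = self._traits(3, 3)
        eig = pd.DataFrame([[1, 1, 1, 0, 0, 0]], index=[1],
                           columns=traits.sample_ids, dtype=float)
        r, p = ck.module_trait_correlation(eig, traits)
        assert r.loc[1, "A"] == pytest.approx(1.0)
        assert p.loc[1, "A"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_gives_p_one(self):
        traits = self._traits(2, 2)
        eig = pd.DataFrame([[1.0, -1.0, 1.0, -1.0]], index=[1],
                           columns=traits.sample_ids)
        r, p = ck.module_trait_correlation(eig, traits)
        assert r.loc[1, "A"] == pytest.approx(0.0, abs=1e-12)
        assert p.loc[1, "A"] == pytest.approx(1.0)

    def test_t_transform_value(self):
        # r = 0.5 at n = 26: t = 0.5 sqrt(24) / sqrt(0.75) ~ 2.828, p ~ 0.0093
        n = 26
        traits = self._traits(13, 13)
        ind = traits.indicator["A"].to_numpy(dtype=float)
        z = ind - ind.mean()
        z = z / np.linalg.norm(z)
        rng = np.random.default_rng(0)
        w = rng.normal(size=n)
        w = w - w.mean() - z * (z @ (w - w.mean()))
        w = w / np.linalg.norm(w)
        eigv = 0.5 * z + np.sqrt(0.75) * w
        eig = pd.DataFrame([eigv], index=[1], columns=traits.sample_ids)
        r, p = ck.module_trait_correlation(eig, traits)
        assert r.loc[1, "A"] == pytest.approx(0.5, abs=1e-9)
        expect_p = 2 * student_t.sf(0.5 * np.sqrt(24) / np.sqrt(0.75), df=24)
        assert p.loc[1, "A"] == pytest.approx(expect_p, rel=1e-9)
        assert expect_p == pytest.approx(0.0093, abs=5e-4)

    def test_too_few_samples(self):
        traits = self._traits(1, 1)
        eig = pd.DataFrame([[0.5, -0.5]], index=[1], columns=traits.sample_ids)
        with pytest.raises(ValidationError):
            ck.module_trait_correlation(eig, traits)


class TestModelAPI:
    def test_fit_is_deterministic(self):
        cfg = ck.SimulationConfig(seed=9, n_genes=900, module_sizes=(40, 40),
                                  n_tissue_specific=5)
        counts, ann, traits, _ = ck.simulate_expression(cfg)
        logtpm = ck.log_transform(ck.compute_tpm(counts, ann))
        sel = ck.select_top_quartile_variance(logtpm)
        sub = logtpm.values.loc[list(sel.selected_gene_ids)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = CoexpressionNetwork(sub, traits).fit()
            r2 = CoexpressionNetwork(sub, traits).fit()
        pd.testing.assert_series_equal(r1.labels, r2.labels)
        pd.testing.assert_frame_equal(r1.eigengenes, r2.eigengenes)
        assert r1.power == r2.power

    def test_summary_mentions_modules(self):
        cfg = ck.SimulationConfig(seed=9, n_genes=900, module_sizes=(40, 40),
                                  n_tissue_specific=5)
        counts, ann, traits, _ = ck.simulate_expression(cfg)
        logtpm = ck.log_transform(ck.compute_tpm(counts, ann))
        sel = ck.select_top_quartile_variance(logtpm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = CoexpressionNetwork(
                logtpm.values.loc[list(sel.selected_gene_ids)], traits).fit()
        text = res.summary()
        assert "modules" in text
        assert str(res.power) in text

    def test_eigengenes_unit_norm(self, small_dataset):
        _, counts, ann, traits, _ = small_dataset
        logtpm = ck.log_transform(ck.compute_tpm(counts, ann))
        sel = ck.select_top_quartile_variance(logtpm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = CoexpressionNetwork(
                logtpm.values.loc[list(sel.selected_gene_ids)], traits,
                NetworkConfig(power=6)).fit()
        for _, row in res.eigengenes.iterrows():
            assert np.linalg.norm(row) == pytest.approx(1.0)
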