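"""Network construction, TOM, clustering, eigengenes, traits, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dysmod import (
    ExpressionDataset,
    SimulationConfig,
    cluster_genes,
    correlation_matrix,
    cut_tree_modules,
    detect_modules,
    eigengenes,
    hub_genes,
    merge_close_modules,
    module_trait_correlation,
    pick_power,
    scale_free_fit,
    simulate_expression,
    soft_threshold_adjacency,
    tom,
)
from dysmod.coexpression import AdjacencyMatrix, ModulePartition

from conftest import partition_from_truth


def random_dataset(rng, n_genes=12, n_samples=9):
    values = pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                          index=[f"g{i:02d}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(n_samples)])
    sheet = pd.DataFrame({"group": ["a"] * n_samples}, index=values.columns)
    return ExpressionDataset(values, sheet)


def powerlaw_adjacency(rng, n=2000, gamma=2.5, kmin=1.0):
    """Symmetric rank-one adjacency whose connectivities follow a power law."""
    k = kmin * rng.random(n) ** (-1.0 / (gamma - 1.0))
    c = k / np.sqrt(k.sum())
    w = np.outer(c, c)
    w /= max(1.0, w.max() * 1.01)  # keep entries in [0, 1]
    np.fill_diagonal(w, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return AdjacencyMatrix(pd.DataFrame(w, index=genes, columns=genes), 1, False)


class TestCorrelation:
    def test_duplicate_and_negated_genes(self, rng):
        base = rng.normal(size=8)
        values = pd.DataFrame([base, base, -base], index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(8)])
        r = correlation_matrix(values)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self, rng):
        values = pd.DataFrame(rng.normal(size=(5, 9)))
        r = correlation_matrix(values).to_numpy()
        x = values.to_numpy()
        for i in range(5):
            for j in range(5):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expect = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert r[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_gene_named(self, rng):
        values = pd.DataFrame(rng.normal(size=(3, 6)), index=["a", "flatgene", "c"])
        values.loc["flatgene"] = 2.0
        with pytest.raises(ValueError, match="flatgene"):
            correlation_matrix(values)

    def test_needs_three_samples(self, rng):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame(rng.normal(size=(4, 2))))


class TestAdjacency:
    def test_power_arithmetic(self):
        cor = pd.DataFrame([[1.0, -0.9], [-0.9, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        unsigned = soft_threshold_adjacency(cor, 6)
        assert unsigned.weights.loc["a", "b"] == pytest.approx(0.9**6)
        cor0 = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"],
                            columns=["a", "b"])
        signed = soft_threshold_adjacency(cor0, 6, signed=True)
        assert signed.weights.loc["a", "b"] == pytest.approx(0.5**6)

    def test_beta_one_unsigned_is_abs(self, rng):
        values = pd.DataFrame(rng.normal(size=(6, 10)))
        cor = correlation_matrix(values)
        adj = soft_threshold_adjacency(cor, 1)
        assert np.allclose(adj.weights, np.abs(cor))

    def test_bounds_and_symmetry(self, rng):
        cor = correlation_matrix(pd.DataFrame(rng.normal(size=(10, 8))))
        for signed in (False, True):
            a = soft_threshold_adjacency(cor, 7, signed).weights.to_numpy()
            assert np.allclose(a, a.T)
            assert a.min() >= 0 and a.max() <= 1
            assert np.allclose(np.diag(a), 1.0)

    def test_invalid_power_rejected(self, rng):
        cor = correlation_matrix(pd.DataFrame(rng.normal(size=(4, 6))))
        with pytest.raises(ValueError):
            soft_threshold_adjacency(cor, 0)


class TestScaleFree:
    def test_powerlaw_connectivities_fit_well(self, rng):
        fit = scale_free_fit(powerlaw_adjacency(rng))
        assert fit.defined
        assert fit.slope < 0
        assert fit.r_squared >= 0.95

    def test_two_genes_undefined(self):
        genes = ["a", "b"]
        w = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=genes, columns=genes)
        fit = scale_free_fit(AdjacencyMatrix(w, 1, False))
        assert not fit.defined and not fit.passes

    def test_positive_slope_never_passes(self):
        from dysmod.coexpression import ScaleFreeFit
        fit = ScaleFreeFit(r_squared=0.99, slope=0.5, defined=True)
        assert not fit.passes


class TestPickPower:
    def test_zero_target_returns_smallest(self, rng):
        # rank-one correlation keeps a power law at every beta -> all pass
        adj = powerlaw_adjacency(rng, n=500)
        cor = adj.weights.copy()
        sel = pick_power(cor, candidate_powers=(2, 4, 6), r2_target=0.0)
        assert sel.beta == 2

    def test_single_candidate(self, rng):
        cor = correlation_matrix(pd.DataFrame(rng.normal(size=(30, 10))))
        sel = pick_power(cor, candidate_powers=(5,), r2_target=0.0)
        assert sel.beta == 5

    def test_deterministic_on_block_simulation(self):
        cfg = SimulationConfig(n_genes=500, module_sizes=(100, 100),
                               group_sizes=(7, 7, 6), factor_loading=0.8,
                               noise_sd=0.6, de_fraction_per_module=0.0,
                               background_de_fraction=0.0, seed=31)
        ds, _ = simulate_expression(cfg)
        cor = correlation_matrix(ds)
        s1 = pick_power(cor)
        s2 = pick_power(cor)
        assert s1.beta == s2.beta
        assert s1.table.equals(s2.table)

    def test_empty_candidates_rejected(self, rng):
        cor = correlation_matrix(pd.DataFrame(rng.normal(size=(4, 6))))
        with pytest.raises(ValueError):
            pick_power(cor, candidate_powers=())


def tom_oracle(a):
    """O(n^3) literal evaluation of the TOM formula."""
    n = a.shape[0]
    t = np.eye(n)
    k = np.array([a[i].sum() - a[i, i] for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            t[i, j] = (l + a[i, j]) / denom if denom > 0 else 0.0
    return t


class TestTOM:
    def test_two_gene_hand_case(self):
        x = 0.37
        genes = ["a", "b"]
        w = pd.DataFrame([[1.0, x], [x, 1.0]], index=genes, columns=genes)
        t = tom(AdjacencyMatrix(w, 1, False))
        assert t.loc["a", "b"] == pytest.approx(x)

    def test_disconnected_network(self):
        genes = list("abcd")
        w = pd.DataFrame(np.eye(4), index=genes, columns=genes)
        t = tom(AdjacencyMatrix(w, 1, False)).to_numpy()
        assert np.allclose(t, np.eye(4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        genes = [f"g{i}" for i in range(n)]
        t = tom(AdjacencyMatrix(pd.DataFrame(a, index=genes, columns=genes),
                                1, False))
        assert np.allclose(t.to_numpy(), tom_oracle(a), atol=1e-10)

    def test_bounds(self, rng):
        cor = correlation_matrix(pd.DataFrame(rng.normal(size=(20, 10))))
        t = tom(soft_threshold_adjacency(cor, 6)).to_numpy()
        assert t.min() >= 0 and t.max() <= 1
        assert np.allclose(t, t.T)


def average_linkage_oracle(d):
    """Naive O(n^3) average-linkage agglomeration; returns merge heights."""
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                h = np.mean([d[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


class TestClustering:
    def test_separated_blocks_merge_within_first(self):
        n1, n2 = 5, 4
        d = np.ones((n1 + n2, n1 + n2))
        d[:n1, :n1] = 0.0
        d[n1:, n1:] = 0.0
        np.fill_diagonal(d, 0.0)
        genes = [f"g{i}" for i in range(n1 + n2)]
        dendro = cluster_genes(pd.DataFrame(d, index=genes, columns=genes))
        heights = dendro.merge[:, 2]
        assert np.allclose(heights[:n1 + n2 - 2], 0.0)
        assert heights[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_merge_heights_equal_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        genes = [f"g{i}" for i in range(n)]
        dendro = cluster_genes(pd.DataFrame(d, index=genes, columns=genes))
        assert np.allclose(np.sort(dendro.merge[:, 2]),
                           np.sort(average_linkage_oracle(d)), atol=1e-10)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 0.3], [0.6, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_genes(d)

    def test_permutation_equivariance(self, block_dataset):
        from sklearn.metrics import adjusted_rand_score
        _, ds, _ = block_dataset
        res1 = detect_modules(ds)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ds.values))
        ds_perm = ExpressionDataset(ds.values.iloc[perm], ds.samples)
        res2 = detect_modules(ds_perm)
        genes = sorted(ds.values.index)
        l1 = [res1.partition.labels[g] for g in genes]
        l2 = [res2.partition.labels[g] for g in genes]
        assert adjusted_rand_score(l1, l2) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def dendro(block_dataset):
    _, ds, _ = block_dataset
    cor = correlation_matrix(ds)
    t = tom(soft_threshold_adjacency(cor, 6))
    return cluster_genes(1.0 - t)


class TestCutTree:

    def test_cut_below_all_merges_unassigns_everything(self, dendro):
        part = cut_tree_modules(dendro, cut_height=0.0, min_module_size=2)
        assert part.n_modules == 0
        assert (part.labels == 0).all()

    def test_cut_above_all_merges_single_module(self, dendro):
        part = cut_tree_modules(dendro, cut_height=dendro.max_height + 1,
                                min_module_size=2)
        assert part.n_modules == 1
        assert (part.labels == 1).all()

    def test_labels_ordered_by_size(self, block_dataset):
        _, ds, truth = block_dataset
        res = detect_modules(ds)
        sizes = [len(res.partition.module_genes(l))
                 for l in res.partition.module_labels]
        assert sizes == sorted(sizes, reverse=True)

    def test_planted_blocks_recovered(self, block_dataset):
        from sklearn.metrics import adjusted_rand_score
        _, ds, truth = block_dataset
        res = detect_modules(ds, min_module_size=20)
        assigned = res.partition.assigned_genes()
        planted = [truth.module_of[g] for g in assigned]
        inferred = [res.partition.labels[g] for g in assigned]
        assert adjusted_rand_score(planted, inferred) >= 0.9


class TestMergeModules:
    def test_zero_threshold_is_identity(self, block_dataset):
        _, ds, truth = block_dataset
        part = partition_from_truth(truth)
        merged = merge_close_modules(ds, part, eigengene_dissim_max=0.0)
        assert (merged.labels == part.labels).all()

    def test_split_block_remerged(self, block_dataset):
        _, ds, truth = block_dataset
        labels = partition_from_truth(truth).labels.copy()
        ones = labels.index[labels == 1]
        labels[ones[:15]] = 3  # artificially split planted block 1
        part = ModulePartition(labels, float("nan"), 0)
        merged = merge_close_modules(ds, part, eigengene_dissim_max=0.25)
        sub = merged.labels[ones]
        assert sub.nunique() == 1
        assert merged.n_modules == 2

    def test_single_module_unchanged(self, block_dataset):
        _, ds, truth = block_dataset
        labels = partition_from_truth(truth).labels.copy()
        labels[labels == 2] = 0
        part = ModulePartition(labels, float("nan"), 0)
        merged = merge_close_modules(ds, part)
        assert merged.n_modules == 1


class TestEigengenes:
    def test_identical_genes_explain_everything(self, rng):
        base = rng.normal(size=10)
        values = pd.DataFrame([base] * 5, index=[f"g{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(10)])
        sheet = pd.DataFrame({"group": ["a"] * 10}, index=values.columns)
        ds = ExpressionDataset(values, sheet)
        labels = pd.Series(1, index=values.index)
        eg = eigengenes(ds, ModulePartition(labels, 0.0, 0))
        assert eg.variance_explained["M1"] == pytest.approx(1.0)

    def test_matches_spectral_oracle(self, rng):
        ds = random_dataset(rng, n_genes=15, n_samples=12)
        labels = pd.Series(1, index=ds.values.index)
        eg = eigengenes(ds, ModulePartition(labels, 0.0, 0))
        # independent oracle: leading eigenvector of the sample-sample
        # cross-product of the standardized matrix
        x = ds.values.to_numpy()
        x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        evals, evecs = np.linalg.eigh(x.T @ x)
        lead = evecs[:, -1]
        e = eg.profiles.loc["M1"].to_numpy()
        assert abs(np.corrcoef(e, lead)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert eg.variance_explained["M1"] == pytest.approx(
            evals[-1] / evals.sum(), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_orientation_rule(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_genes=10, n_samples=8)
        labels = pd.Series(1, index=ds.values.index)
        eg = eigengenes(ds, ModulePartition(labels, 0.0, 0))
        x = ds.values.to_numpy()
        x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        c = np.corrcoef(eg.profiles.loc["M1"], x.mean(0))[0, 1]
        assert c >= 0
        assert np.linalg.norm(eg.profiles.loc["M1"]) == pytest.approx(1.0)

    def test_tiny_module_rejected(self, rng):
        ds = random_dataset(rng, n_genes=3, n_samples=8)
        labels = pd.Series([1, 2, 2], index=ds.values.index)
        with pytest.raises(ValueError):
            eigengenes(ds, ModulePartition(labels, 0.0, 0))


@pytest.fixture(scope="module")
def eg(block_dataset):
    _, ds, truth = block_dataset
    return ds, eigengenes(ds, partition_from_truth(truth))


class TestModuleTrait:

    def test_trait_equal_to_eigengene(self, eg):
        ds, eigs = eg
        traits = pd.DataFrame({"self": eigs.profiles.loc["M1"].to_numpy()},
                              index=ds.values.columns)
        table = module_trait_correlation(eigs, traits)
        row = table[(table["module"] == "M1") & (table["trait"] == "self")]
        assert row["r"].iloc[0] == pytest.approx(1.0)
        assert row["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_student_transform_oracle(self, eg):
        ds, eigs = eg
        rng = np.random.default_rng(8)
        traits = pd.DataFrame({"noise": rng.normal(size=ds.values.shape[1])},
                              index=ds.values.columns)
        table = module_trait_correlation(eigs, traits)
        n = ds.values.shape[1]
        for _, row in table.iterrows():
            r = row["r"]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            assert row["p"] == pytest.approx(2 * stats.t.sf(abs(t), n - 2),
                                             rel=1e-10)

    def test_orthogonal_trait_small_r(self, block_dataset):
        _, ds, truth = block_dataset
        eigs = eigengenes(ds, partition_from_truth(truth))
        n = ds.values.shape[1]
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            traits = pd.DataFrame({"x": rng.normal(size=n)},
                                  index=ds.values.columns)
            t = module_trait_correlation(eigs, traits)
            rs.append(abs(t["r"].iloc[0]))
        assert np.mean(rs) < 3 / np.sqrt(n)

    def test_constant_trait_flagged(self, eg):
        ds, eigs = eg
        traits = pd.DataFrame({"const": np.ones(ds.values.shape[1])},
                              index=ds.values.columns)
        table = module_trait_correlation(eigs, traits)
        assert table["undefined"].all()
        assert table["r"].isna().all()


class TestHubGenes:
    def test_identical_module_hub_is_smallest_id(self, rng):
        base = rng.normal(size=12)
        values = pd.DataFrame([base] * 4, index=["g3", "g1", "g4", "g2"],
                              columns=[f"s{i}" for i in range(12)])
        sheet = pd.DataFrame({"group": ["a"] * 12}, index=values.columns)
        ds = ExpressionDataset(values, sheet)
        labels = pd.Series(1, index=values.index)
        part = ModulePartition(labels, 0.0, 0)
        hubs = hub_genes(ds, part, eigengenes(ds, part))
        top = hubs[hubs["is_hub"]]
        assert list(top["gene"]) == ["g1"]
        assert np.allclose(hubs["kME"], 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_strongest_loading_is_hub(self, seed):
        rng = np.random.default_rng(seed)
        n_s = 40
        f = rng.normal(size=n_s)
        rows = {"g_strong": f + 0.05 * rng.normal(size=n_s)}
        for i in range(9):
            rows[f"g_weak{i}"] = 0.5 * f + rng.normal(size=n_s)
        values = pd.DataFrame(rows).T
        values.columns = [f"s{i}" for i in range(n_s)]
        sheet = pd.DataFrame({"group": ["a"] * n_s}, index=values.columns)
        ds = ExpressionDataset(values, sheet)
        labels = pd.Series(1, index=values.index)
        part = ModulePartition(labels, 0.0, 0)
        hubs = hub_genes(ds, part, eigengenes(ds, part))
        assert hubs.loc[hubs["is_hub"], "gene"].iloc[0] == "g_strong"

    def test_outside_gene_absent(self, block_dataset):
        _, ds, truth = block_dataset
        part = partition_from_truth(truth)
        hubs = hub_genes(ds, part, eigengenes(ds, part))
        m1 = set(hubs.loc[hubs["module"] == 1, "gene"])
        assert m1 == set(truth.module_genes(1))
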