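"""Network core: signed adjacency values, TOM against a brute-force oracle,
scale-free fit, tree-cut module detection, eigengenes vs SVD, merging, and
module-trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import heteronet as hn
from heteronet.network import (GREY, CoexpressionModules, NetworkConfig,
                               scale_free_fit_index)
from tests.conftest import make_expression


def random_adjacency(rng, n):
    """Symmetric adjacency with unit diagonal and entries in [0, 1]."""
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                        columns=[f"g{i}" for i in range(n)])


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Brute-force double-loop TOM, independent of the vectorized path."""
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (num + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


class TestSignedAdjacency:
    def test_correlation_extremes(self):
        r = pd.DataFrame([[1.0, 1.0, -1.0],
                          [1.0, 1.0, -1.0],
                          [-1.0, -1.0, 1.0]],
                         index=list("abc"), columns=list("abc"))
        a = hn.signed_adjacency(None, beta=7, r=r)
        assert a.loc["a", "b"] == pytest.approx(1.0)
        assert a.loc["a", "c"] == pytest.approx(0.0)

    def test_zero_correlation_at_power_16(self):
        r = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        a = hn.signed_adjacency(None, beta=16, r=r)
        assert a.loc["a", "b"] == pytest.approx(1.52588e-5, rel=1e-4)

    def test_constant_gene_error_names_gene(self):
        vals = np.vstack([np.ones(6), np.arange(6, dtype=float)])
        with pytest.raises(ValueError, match="g0"):
            hn.signed_adjacency(make_expression(vals).log2(), beta=6)

    def test_range_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(0)
        x = make_expression(rng.exponential(1.0, size=(15, 10)))
        a = hn.signed_adjacency(x.log2(), beta=5)
        assert ((a.values >= 0) & (a.values <= 1)).all()
        np.testing.assert_allclose(a.values, a.values.T)
        np.testing.assert_allclose(np.diag(a), 1.0)


class TestTopologicalOverlap:
    @pytest.mark.parametrize("a_val", [0.1, 0.4, 0.9])
    def test_three_gene_uniform_closed_form(self, a_val):
        # all off-diagonal adjacencies equal to a -> TOM_ij = a
        adj = random_adjacency(np.random.default_rng(0), 3)
        adj.values[:] = a_val
        np.fill_diagonal(adj.values, 1.0)
        tom = hn.topological_overlap(adj)
        off = tom.values[np.triu_indices(3, k=1)]
        np.testing.assert_allclose(off, a_val, rtol=1e-12)

    def test_complete_unit_adjacency_gives_all_ones(self):
        adj = random_adjacency(np.random.default_rng(0), 6)
        adj.values[:] = 1.0
        np.testing.assert_allclose(hn.topological_overlap(adj).values, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(5, 11))
            adj = random_adjacency(rng, n)
            tom = hn.topological_overlap(adj).to_numpy()
            np.testing.assert_allclose(tom, tom_oracle(adj.to_numpy()),
                                       atol=1e-12)

    def test_range_and_symmetry(self):
        adj = random_adjacency(np.random.default_rng(2), 12)
        tom = hn.topological_overlap(adj)
        assert ((tom.values >= 0) & (tom.values <= 1 + 1e-12)).all()
        np.testing.assert_allclose(tom.values, tom.values.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestScaleFreeFit:
    def test_exact_power_law_scores_one(self):
        # multiplicities n_v = 2520 / v for v = 1..10 give p(k) ~ k^-1
        # exactly, with each value its own equal-width bin
        k = np.concatenate([np.full(2520 // v, float(v)) for v in range(1, 11)])
        assert scale_free_fit_index(k, n_bins=10) == pytest.approx(1.0, abs=1e-9)

    def test_increasing_degree_distribution_scores_negative(self):
        k = np.concatenate([np.full(v * 10, float(v)) for v in range(1, 11)])
        assert scale_free_fit_index(k, n_bins=10) < 0

    def test_mean_connectivity_strictly_decreasing_in_power(self, module_dataset):
        x, _ = module_dataset
        scan, _ = hn.scale_free_fit(x.log2().iloc[:150], powers=range(1, 11))
        assert (np.diff(scan["mean_connectivity"]) < 0).all()

    def test_chosen_power_matches_independent_scan(self, module_dataset):
        """Chosen beta within +/-4 of an independently coded exhaustive scan
        (naive loops, same selection rule)."""
        x, _ = module_dataset
        frame = x.log2().iloc[:200]
        scan, chosen = hn.scale_free_fit(frame, powers=range(1, 31))
        # oracle: naive reimplementation
        vals = frame.to_numpy()
        r = np.corrcoef(vals)
        best_power, best_r2, first_reaching = None, -np.inf, None
        for beta in range(1, 31):
            a = ((1 + r) / 2.0) ** beta
            np.fill_diagonal(a, 1.0)
            k = a.sum(axis=0) - 1.0
            k = k[k > 0]
            edges = np.linspace(k.min(), k.max(), 11)
            xs, ys = [], []
            for b in range(10):
                lo, hi = edges[b], edges[b + 1]
                sel = (k >= lo) & (k < hi) if b < 9 else (k >= lo) & (k <= hi)
                if sel.sum() == 0:
                    continue
                xs.append(np.log10(k[sel].mean()))
                ys.append(np.log10(sel.sum() / k.size))
            xs, ys = np.array(xs), np.array(ys)
            slope = np.polyfit(xs, ys, 1)[0]
            r2 = np.corrcoef(xs, ys)[0, 1] ** 2
            signed = -np.sign(slope) * r2
            if signed >= 0.8 and first_reaching is None:
                first_reaching = beta
            if signed > best_r2:
                best_r2, best_power = signed, beta
        oracle = first_reaching if first_reaching is not None else best_power
        assert abs(chosen - oracle) <= 4


class TestCutModules:
    def test_two_planted_blocks_recovered_exactly(self):
        x, truth = hn.simulate_single_dataset(
            seed=7, n_genes=120, module_sizes=(60, 60), module_cor=0.8,
            n_samples=30)
        adj = hn.signed_adjacency(x.log2(), 12)
        part = hn.cut_modules(1.0 - hn.topological_overlap(adj),
                              NetworkConfig(power=12))
        assert adjusted_rand_score(truth, part.labels) == pytest.approx(1.0)

    def test_small_block_forced_grey_by_min_size(self):
        x, _ = hn.simulate_single_dataset(
            seed=8, n_genes=40, module_sizes=(40,), module_cor=0.8,
            n_samples=30)
        adj = hn.signed_adjacency(x.log2(), 12)
        part = hn.cut_modules(1.0 - hn.topological_overlap(adj),
                              NetworkConfig(power=12, min_module_size=50))
        assert (part.labels == GREY).all()

    def test_pure_noise_stays_mostly_grey(self):
        grey_fracs = []
        for seed in range(20):
            x, _ = hn.simulate_single_dataset(
                seed=100 + seed, n_genes=200, module_sizes=(),
                module_cor=0.0, n_samples=30)
            adj = hn.signed_adjacency(x.log2(), 12)
            part = hn.cut_modules(1.0 - hn.topological_overlap(adj),
                                  NetworkConfig(power=12, min_module_size=50))
            grey_fracs.append((part.labels == GREY).mean())
        assert np.mean(grey_fracs) >= 0.90

    def test_labels_assigned_by_decreasing_size(self, module_dataset):
        x, truth = module_dataset
        model = CoexpressionModules(power=12, deep_split=2).fit(x)
        sizes = model.labels_[model.labels_ != GREY].value_counts()
        palette_order = [c for c in hn.network.MODULE_COLORS if c in sizes.index]
        assert list(sizes.sort_values(ascending=False).index[:3]) \
            == palette_order[:3]


class TestModuleEigengenes:
    def test_identical_genes_give_variance_one(self):
        base = np.linspace(1.0, 9.0, 12)
        x = make_expression(np.vstack([base] * 5))
        labels = pd.Series("blue", index=x.genes)
        mes, var = hn.module_eigengenes(x.log2(), labels)
        assert var["blue"] == pytest.approx(1.0)
        z = (np.log2(base + 1) - np.log2(base + 1).mean())
        z = z / np.std(z, ddof=1)
        np.testing.assert_allclose(np.abs(mes["blue"]),
                                   np.abs(z / np.linalg.norm(z)), atol=1e-10)

    def test_sign_aligned_with_mean_profile(self, module_dataset):
        x, truth = module_dataset
        mes, _ = hn.module_eigengenes(x.log2(), truth)
        frame = x.log2()
        for module in mes.columns:
            sub = frame.loc[truth.index[truth == module]]
            z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
            assert np.corrcoef(mes[module], z.mean(axis=0))[0, 1] >= 0

    def test_matches_direct_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(9)
        x = make_expression(rng.exponential(2.0, size=(20, 15)))
        labels = pd.Series("red", index=x.genes)
        mes, var = hn.module_eigengenes(x.log2(), labels)
        z = x.log2()
        z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1, ddof=1), axis=0)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        assert (np.allclose(mes["red"], vt[0], atol=1e-10)
                or np.allclose(mes["red"], -vt[0], atol=1e-10))
        assert var["red"] == pytest.approx(s[0] ** 2 / (s ** 2).sum())

    def test_eigengenes_unit_norm(self, module_dataset):
        x, truth = module_dataset
        mes, _ = hn.module_eigengenes(x.log2(), truth)
        np.testing.assert_allclose(np.linalg.norm(mes, axis=0), 1.0)


def correlated_module_data(cors, n_samples=60, genes_per_module=20, seed=0):
    """Expression whose module eigengenes have approximately the requested
    pairwise correlations (factors built by Cholesky)."""
    rng = np.random.default_rng(seed)
    m = len(cors)
    cov = np.array([[1.0 if i == j else cors[min(i, j)][max(i, j)]
                     for j in range(m)] for i in range(m)])
    factors = rng.standard_normal((n_samples, m)) @ np.linalg.cholesky(cov).T
    rows, labels = [], []
    for k in range(m):
        for g in range(genes_per_module):
            rows.append(0.95 * factors[:, k] + 0.3 * rng.standard_normal(n_samples))
            labels.append(f"mod{k}")
    vals = np.exp2(5.0 + np.array(rows))
    x = make_expression(vals)
    return x, pd.Series(labels, index=x.genes)


class TestMergeCloseModules:
    def test_highly_correlated_modules_merge(self):
        cors = {0: {1: 0.95}, 1: {}}
        x, labels = correlated_module_data(cors, seed=1)
        merged, mes, _ = hn.merge_close_modules(x.log2(), labels, 0.25)
        assert merged.nunique() == 1

    def test_distant_modules_untouched(self):
        cors = {0: {1: 0.5}, 1: {}}
        x, labels = correlated_module_data(cors, seed=2)
        merged, mes, _ = hn.merge_close_modules(x.log2(), labels, 0.25)
        assert merged.nunique() == 2

    def test_chain_converges_to_stable_fixpoint(self):
        cors = {0: {1: 0.85, 2: 0.5}, 1: {2: 0.85}, 2: {}}
        x, labels = correlated_module_data(cors, seed=3)
        merged1, _, _ = hn.merge_close_modules(x.log2(), labels, 0.25)
        merged2, _, _ = hn.merge_close_modules(x.log2(), merged1, 0.25)
        pd.testing.assert_series_equal(merged1, merged2)
        rerun, _, _ = hn.merge_close_modules(x.log2(), labels, 0.25)
        pd.testing.assert_series_equal(merged1, rerun)


class TestCorPvalueStudent:
    def test_zero_correlation_gives_p_one(self):
        assert hn.cor_pvalue_student(0.0, 10) == pytest.approx(1.0)

    def test_hand_example(self):
        # r = 0.9, n = 12: t = 6.529, p = 6.6e-5
        p = hn.cor_pvalue_student(0.9, 12)
        t = 0.9 * np.sqrt(10) / np.sqrt(1 - 0.81)
        assert t == pytest.approx(6.529, abs=2e-3)
        assert p == pytest.approx(6.6e-5, rel=0.02)

    def test_perfect_correlation_clamps_to_zero(self):
        assert hn.cor_pvalue_student(1.0, 5) == 0.0
        assert hn.cor_pvalue_student(-1.0, 5) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hn.cor_pvalue_student(0.5, 2)


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene(self, module_dataset):
        x, truth = module_dataset
        mes, _ = hn.module_eigengenes(x.log2(), truth)
        traits = pd.DataFrame({"EN": mes.iloc[:, 0]}, index=mes.index)
        table = hn.module_trait_correlation(mes, traits)
        top = table.loc[table["module"] == mes.columns[0]].iloc[0]
        assert top["r"] == pytest.approx(1.0)
        assert top["p"] < 1e-100

    def test_planted_trait_recovers_module(self):
        hits = 0
        for seed in range(20):
            x, truth = hn.simulate_single_dataset(
                seed=300 + seed, n_genes=300, module_sizes=(100, 100),
                module_cor=0.6, n_samples=30)
            mes, _ = hn.module_eigengenes(x.log2(), truth)
            rng = np.random.default_rng(seed)
            trait = mes["M1"] + rng.normal(0, 1 / (3 * np.sqrt(30)), 30)
            table = hn.module_trait_correlation(
                mes, pd.DataFrame({"EN": trait}, index=mes.index))
            best = table.loc[table["r"].abs().idxmax(), "module"]
            hits += best == "M1"
        assert hits >= 19

    def test_permuted_trait_rarely_significant(self, module_dataset):
        x, truth = module_dataset
        mes, _ = hn.module_eigengenes(x.log2(), truth)
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(30):
            trait = pd.DataFrame({"EN": rng.permutation(mes.iloc[:, 0].to_numpy())},
                                 index=mes.index)
            table = hn.module_trait_correlation(mes, trait)
            rates.append(table["significant"].mean())
        assert np.mean(rates) < 0.15

    def test_misaligned_samples_rejected(self, module_dataset):
        x, truth = module_dataset
        mes, _ = hn.module_eigengenes(x.log2(), truth)
        traits = pd.DataFrame({"EN": np.arange(len(mes))},
                              index=[f"other{i}" for i in range(len(mes))])
        with pytest.raises(ValueError, match="aligned"):
            hn.module_trait_correlation(mes, traits)


class TestEstimator:
    def test_planted_module_recovery_ari(self, module_dataset):
        # recovery of the planted modules; background genes that attach to a
        # module's periphery are not part of the planted truth
        x, truth = module_dataset
        model = CoexpressionModules(power=12, deep_split=2).fit(x)
        mask = truth != "background"
        assert adjusted_rand_score(truth[mask], model.labels_[mask]) >= 0.8

    def test_sklearn_params_roundtrip(self):
        model = CoexpressionModules(power=8, min_module_size=30)
        params = model.get_params()
        assert params["power"] == 8
        clone = CoexpressionModules(**params)
        assert clone.get_params() == params
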