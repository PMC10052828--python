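"""Co-expression network stage: TMM, INT, bicor, TOM, modules, kDiff."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from isletdecon import network, synth
from isletdecon.errors import ValidationError


def random_counts(rng, n_samples=6, n_genes=300, depth=2000):
    lam = rng.gamma(2.0, 5.0, n_genes)
    return pd.DataFrame(
        rng.poisson(lam * depth / lam.sum(), size=(n_samples, n_genes)),
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"g{i}" for i in range(n_genes)],
    )


class TestTMM:
    def test_identical_samples_get_unit_factors(self, rng):
        counts = random_counts(rng, n_samples=1)
        counts = pd.concat([counts, counts.set_axis(["S1"])])
        factors = network.tmm_factors(counts)
        assert np.allclose(factors, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self, rng):
        base = random_counts(rng, n_samples=1)
        doubled = (base * 2).set_axis(["S1"])
        counts = pd.concat([base, doubled])
        factors = network.tmm_factors(counts)
        assert np.allclose(factors, 1.0, atol=1e-9)

    def test_high_count_monopolizing_genes_push_factor_below_one(self, rng):
        base = random_counts(rng, n_samples=1, n_genes=400, depth=40_000) + 1
        other = base.copy().set_axis(["S1"])
        up = rng.choice(400, size=20, replace=False)  # 5% of genes 8-fold up
        other.iloc[0, up] *= 8
        counts = pd.concat([base, other])
        factors = network.tmm_factors(counts, reference="S0")
        # geometric-mean normalization spreads the shift over both samples
        assert factors["S1"] < factors["S0"]

    def test_zero_library_rejected(self, rng):
        counts = random_counts(rng, n_samples=3)
        counts.iloc[1] = 0
        with pytest.raises(ValidationError):
            network.tmm_factors(counts)

    def test_normalize_bulk_returns_log2_cpm_scale(self, rng):
        counts = random_counts(rng, n_samples=4)
        out = network.normalize_bulk(counts)
        assert out.shape == counts.shape
        assert np.isfinite(out.to_numpy()).all()


class TestInverseNormalTransform:
    def test_monotone_transform_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(15, 6)))
        a = network.inverse_normal_transform(expr)
        b = network.inverse_normal_transform(np.exp(expr))
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_five_distinct_values_match_blom_closed_form(self):
        expr = pd.DataFrame({"g": [3.0, 1.0, 4.0, 1.5, 9.0]})
        out = network.inverse_normal_transform(expr)["g"].to_numpy()
        ranks = stats.rankdata([3.0, 1.0, 4.0, 1.5, 9.0])
        expected = stats.norm.ppf((ranks - 3 / 8) / (5 + 1 / 4))
        assert np.allclose(out, expected)

    def test_two_of_three_symmetric_about_zero(self):
        out = network.inverse_normal_transform(pd.DataFrame({"g": [1.0, 2.0, 3.0]}))
        v = out["g"].to_numpy()
        assert v[0] == pytest.approx(-v[2])
        assert v[1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_zeroed_with_warning(self):
        expr = pd.DataFrame({"g": [2.0, 2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = network.inverse_normal_transform(expr)
        assert np.all(out.to_numpy() == 0)


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=50)
        assert network.bicor(x, x) == pytest.approx(1.0)

    def test_affine_invariance_with_sign(self, rng):
        x = rng.normal(size=50)
        assert network.bicor(x, 2.0 + 3.0 * x) == pytest.approx(1.0)
        assert network.bicor(x, 2.0 - 3.0 * x) == pytest.approx(-1.0)

    def test_close_to_pearson_without_outliers(self, rng):
        cov = [[1, 0.8], [0.8, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        b = network.bicor(xy[:, 0], xy[:, 1])
        r = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        assert abs(b - r) < 0.1

    def test_robust_to_single_outlier(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(0, 0.3, 100)
        y_out = y.copy()
        y_out[0] = 50.0
        assert abs(network.bicor(x, y_out) - network.bicor(x, y)) < 0.1

    def test_mad_zero_falls_back_to_pearson(self):
        # both vectors have MAD = 0, so both columns use the Pearson fallback
        x = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 2.0])
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.1, 2.2])
        with pytest.warns(UserWarning, match="MAD"):
            b = network.bicor(x, y)
        assert abs(b - np.corrcoef(x, y)[0, 1]) < 1e-6

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            network.bicor(np.ones(3), np.ones(3))


class TestSoftThreshold:
    def test_power_zero_excluded(self, rng):
        expr, _, _ = synth.simulate_coexpression(20, {"M1": 15}, 15, seed=0)
        cor = network.bicor_matrix(expr)
        power, table = network.pick_soft_threshold(cor, candidate_powers=[0, 2, 4])
        assert 0 not in table.power.tolist()

    def test_returned_power_is_smallest_reaching_target(self, rng):
        expr, _, _ = synth.simulate_coexpression(
            30, {"M1": 30, "M2": 30, "M3": 30}, 60, within_r=0.8, seed=1
        )
        cor = network.bicor_matrix(expr)
        power, table = network.pick_soft_threshold(cor, r2_target=0.8)
        reached = table[table.signed_r2 >= 0.8]
        if len(reached):
            assert power == reached.power.iloc[0]
        else:
            assert power == table.loc[table.signed_r2.idxmax(), "power"]

    def test_adjacency_monotone_decreasing_in_power(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 8)))
        cor = network.bicor_matrix(expr)
        a2 = network.adjacency_matrix(cor, 2)
        a4 = network.adjacency_matrix(cor, 4)
        off = ~np.eye(8, dtype=bool)
        assert np.all(np.asarray(a4)[off] <= np.asarray(a2)[off] + 1e-15)


def brute_force_tom(a):
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTOM:
    def test_exclusive_pair_has_full_overlap(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        tom = network.tom_matrix(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_unconnected_pair_without_shared_neighbors_is_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        tom = network.tom_matrix(a)
        assert tom[0, 2] == 0.0

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(3):
            c = rng.uniform(0, 1, size=(10, 10))
            a = (c + c.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = network.tom_matrix(a)
            assert np.allclose(tom, brute_force_tom(a), atol=1e-12)

    def test_symmetry_and_range(self, rng):
        c = rng.uniform(0, 1, size=(20, 20))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = np.asarray(network.tom_matrix(a))
        assert np.allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_out_of_range_adjacency_rejected(self):
        with pytest.raises(ValidationError):
            network.tom_matrix(np.array([[0.0, 1.5], [1.5, 0.0]]))


class TestModules:
    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        expr, _, labels = synth.simulate_coexpression(
            40, {"M1": 20, "M2": 20}, 0, within_r=0.9, seed=2
        )
        net = network.build_network(expr, power=8)
        ari = adjusted_rand_score(labels.to_numpy(), net.module_labels.to_numpy())
        assert ari == 1.0

    def test_noise_genes_stay_unassigned(self):
        unassigned_frac = []
        for seed in range(10):
            expr, _, _ = synth.simulate_coexpression(
                24, {}, 60, within_r=0.0, seed=seed
            )
            net = network.build_network(expr, power=8)
            unassigned_frac.append((net.module_labels == "unassigned").mean())
        assert np.mean([f >= 0.9 for f in unassigned_frac]) >= 0.9

    def test_gene_order_permutation_permutes_labels(self, rng):
        expr, _, _ = synth.simulate_coexpression(30, {"M1": 10, "M2": 10}, 5, seed=3)
        net = network.build_network(expr, power=8)
        perm = rng.permutation(expr.shape[1])
        net_p = network.build_network(expr.iloc[:, perm], power=8)
        assert net_p.module_labels.sort_index().equals(net.module_labels.sort_index())


class TestEigengene:
    def test_identical_genes_give_their_shared_profile(self, rng):
        profile = rng.normal(size=20)
        expr = pd.DataFrame({f"g{i}": profile for i in range(5)})
        labels = pd.Series("M1", index=expr.columns)
        eg = network.eigengene(expr, labels)["M1"]
        assert abs(np.corrcoef(eg, profile)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eg, profile)[0, 1] > 0  # sign aligned

    def test_sign_convention_stable_under_global_flip(self, rng):
        expr, _, labels = synth.simulate_coexpression(20, {"M1": 8}, 0, seed=4)
        eg = network.eigengene(expr, labels)["M1"]
        eg_flip = network.eigengene(-expr, labels)["M1"]
        assert np.corrcoef(eg, -eg_flip)[0, 1] == pytest.approx(1.0)

    def test_pc1_captures_planted_rank_one_structure(self, rng):
        z = rng.normal(size=30)
        expr = pd.DataFrame(
            {f"g{i}": z + rng.normal(0, 0.3, 30) for i in range(10)}
        )
        labels = pd.Series("M1", index=expr.columns)
        eg = network.eigengene(expr, labels)["M1"]
        assert abs(np.corrcoef(eg, z)[0, 1]) > np.sqrt(0.7)


class TestModuleTrait:
    def test_perfect_correlation_detected(self, rng):
        eg = pd.DataFrame({"M1": rng.normal(size=20)})
        traits = pd.DataFrame({"t": eg["M1"].to_numpy()}, index=eg.index)
        out = network.module_trait(eg, traits)
        assert out.pearson_r.iloc[0] == pytest.approx(1.0)
        assert out.p_value.iloc[0] < 1e-12

    def test_r_antisymmetric_under_trait_negation(self, rng):
        eg = pd.DataFrame({"M1": rng.normal(size=16)})
        t = rng.normal(size=16)
        a = network.module_trait(eg, pd.DataFrame({"t": t}, index=eg.index))
        b = network.module_trait(eg, pd.DataFrame({"t": -t}, index=eg.index))
        assert a.pearson_r.iloc[0] == pytest.approx(-b.pearson_r.iloc[0])

    def test_constant_trait_excluded_with_warning(self, rng):
        eg = pd.DataFrame({"M1": rng.normal(size=10)})
        traits = pd.DataFrame({"t": np.ones(10)}, index=eg.index)
        with pytest.warns(UserWarning, match="constant"):
            out = network.module_trait(eg, traits)
        assert out.empty

    def test_fdr_null_false_positive_rate(self):
        """Independent noise traits: FP pairs near the nominal FDR budget."""
        fp = 0
        n_pairs = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            eg = pd.DataFrame(rng.normal(size=(20, 10)), columns=[f"M{i}" for i in range(10)])
            traits = pd.DataFrame(rng.normal(size=(20, 4)), index=eg.index,
                                  columns=list("wxyz"))
            out = network.module_trait(eg, traits)
            fp += int(out.significant.sum())
            n_pairs += len(out)
        expected = 0.05 * n_pairs  # BH bound under independence
        assert fp <= expected + 3 * np.sqrt(expected)


class TestModuleMembership:
    def test_member_genes_of_rank_one_module_have_high_kme(self, rng):
        z = rng.normal(size=25)
        expr = pd.DataFrame({f"g{i}": z + rng.normal(0, 0.2, 25) for i in range(6)})
        labels = pd.Series("M1", index=expr.columns)
        eg = network.eigengene(expr, labels)
        kme = network.module_membership(expr, eg)
        assert (kme["M1"].abs() > 0.9).all()
        assert ((kme >= -1) & (kme <= 1)).all().all()

    def test_kme_tracks_gene_trait_correlation_in_linked_module(self):
        """|kME| and |gene-trait r| rank-correlate in a trait-linked module."""
        expr, traits, labels = synth.simulate_coexpression(
            32, {"M1": 40}, 0, within_r=0.6, trait_effects={"M1": 0.8}, seed=6
        )
        eg = network.eigengene(expr, labels)
        kme = network.module_membership(expr, eg)["M1"]
        gt = network.gene_trait_correlations(expr, traits)["trait"]
        rho = stats.spearmanr(kme.abs(), gt.abs()).statistic
        assert rho > 0.5


class TestConnectivity:
    def test_singleton_module_has_zero_k_within(self):
        adj = pd.DataFrame(np.ones((3, 3)) * 0.5, index=list("abc"), columns=list("abc"))
        labels = pd.Series(["M1", "M1", "M2"], index=list("abc"))
        kw = network.k_within(adj, labels)
        assert kw["c"] == 0.0

    def test_uniform_module_closed_form(self):
        m, a = 5, 0.3
        adj = pd.DataFrame(np.full((m, m), a), index=range(m), columns=range(m))
        labels = pd.Series("M1", index=range(m))
        kw = network.k_within(adj, labels)
        assert np.allclose(kw, (m - 1) * a)

    def test_matches_brute_force_restricted_row_sum(self, rng):
        n = 5
        c = rng.uniform(0, 1, size=(n, n))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 0.0)
        adj = pd.DataFrame(a, index=range(n), columns=range(n))
        labels = pd.Series(["M1", "M1", "M1", "M2", "M2"], index=range(n))
        kw = network.k_within(adj, labels)
        for i in range(n):
            expected = sum(
                a[i, j] for j in range(n) if j != i and labels[j] == labels[i]
            )
            assert kw[i] == pytest.approx(expected)


class TestKDiff:
    def test_boundary_and_threshold_conventions(self):
        assert network.kdiff(np.array([10.0]), np.array([0.0]))[0] == 1.0
        assert network.kdiff(np.array([5.0]), np.array([5.0]))[0] == 0.0
        assert network.kdiff(np.array([3.0]), np.array([1.0]))[0] == pytest.approx(0.5)
        assert np.isnan(network.kdiff(np.array([0.0]), np.array([0.0]))[0])

    def test_three_one_is_not_flagged_under_strict_threshold(self, rng):
        n = 4
        adj_a = pd.DataFrame(np.zeros((n, n)), index=range(n), columns=range(n))
        adj_b = adj_a.copy()
        # gene 0: k_a = 3, k_b = 1 within its module
        adj_a.iloc[0, 1] = adj_a.iloc[1, 0] = 1.0
        adj_a.iloc[0, 2] = adj_a.iloc[2, 0] = 1.0
        adj_a.iloc[0, 3] = adj_a.iloc[3, 0] = 1.0
        adj_b.iloc[0, 1] = adj_b.iloc[1, 0] = 1.0
        labels = pd.Series("M1", index=range(n))
        out = network.differential_connectivity_from_adjacency(adj_a, adj_b, labels)
        assert out.loc[0, "k_diff"] == pytest.approx(0.5)
        assert not bool(out.loc[0, "flagged"])

    def test_vectorized_equals_brute_force(self, rng):
        n = 50
        def random_adj():
            c = rng.uniform(0, 1, size=(n, n))
            a = (c + c.T) / 2
            np.fill_diagonal(a, 0.0)
            return pd.DataFrame(a, index=range(n), columns=range(n))

        adj_a, adj_b = random_adj(), random_adj()
        labels = pd.Series(rng.choice(["M1", "M2", "M3"], size=n), index=range(n))
        out = network.differential_connectivity_from_adjacency(adj_a, adj_b, labels)
        for g in range(n):
            same = [h for h in range(n) if h != g and labels[h] == labels[g]]
            ka = sum(adj_a.iloc[g, h] for h in same)
            kb = sum(adj_b.iloc[g, h] for h in same)
            expected = (ka - kb) / (ka + kb)
            assert out.loc[g, "k_diff"] == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_cohort_swap(self, seed):
        rng = np.random.default_rng(seed)
        k_a = rng.uniform(0, 10, 20)
        k_b = rng.uniform(0, 10, 20)
        assert np.allclose(network.kdiff(k_a, k_b), -network.kdiff(k_b, k_a))

    def test_planted_decorrelation_is_flagged(self):
        """Genes correlated in cohort A but not B get |kDiff| > 0.5."""
        hits, total = 0, 0
        for seed in range(5):
            expr_a, _, labels = synth.simulate_coexpression(
                16, {"M1": 15}, 0, within_r=0.9, seed=seed
            )
            rng = np.random.default_rng(1000 + seed)
            expr_b = pd.DataFrame(
                rng.normal(size=expr_a.shape), index=expr_a.index, columns=expr_a.columns
            )
            out = network.differential_connectivity(expr_a, expr_b, labels, power=8)
            hits += int(out.flagged.sum())
            total += len(out)
        assert hits / total >= 0.9

    def test_mismatched_gene_sets_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        b = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abce"))
        labels = pd.Series("M1", index=list("abcd"))
        with pytest.raises(ValidationError):
            network.differential_connectivity(a, b, labels)


class TestEdgeList:
    def test_min_weight_filter_and_shape(self, rng):
        n = 6
        c = rng.uniform(0, 1, size=(n, n))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 0.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        edges = network.edge_list(adj, min_weight=0.5)
        assert (edges.adjacency >= 0.5).all()
        full = network.edge_list(adj, min_weight=0.0)
        assert len(full) == n * (n - 1) // 2
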