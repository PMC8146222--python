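import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_adjacency
from lncscreen.expression import log_transform
from lncscreen.network import (
    DegenerateDegreeDistribution,
    connectivity,
    correlation_matrix,
    diss_tom,
    pick_soft_threshold,
    scale_free_fit,
    scaled_intramodular_degree,
    signed_adjacency,
    topological_overlap,
)
from lncscreen.simulate import ModuleSpec, SimulationConfig, \
    simulate_modular_expression


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference implementation of the topological overlap."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


class TestCorrelation:
    def test_duplicated_and_negated_gene(self, rng):
        base = rng.standard_normal(6)
        mat = pd.DataFrame([base, base, -base + 3.0],
                           index=["g1", "g1copy", "g1neg"],
                           columns=[f"s{j}" for j in range(6)])
        cor = correlation_matrix(mat)
        assert cor.loc["g1", "g1copy"] == pytest.approx(1.0)
        assert cor.loc["g1", "g1neg"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        mat = pd.DataFrame(rng.standard_normal((4, 6)),
                           index=[f"g{i}" for i in range(4)],
                           columns=[f"s{j}" for j in range(6)])
        cor = correlation_matrix(mat)
        x = mat.to_numpy()
        n = x.shape[1]
        for i in range(4):
            for j in range(4):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi @ xj / (n - 1)) / (xi.std(ddof=1) * xj.std(ddof=1))
                assert cor.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                           index=["ok", "flat"], columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(mat)
        cor = correlation_matrix(mat, strict=False)
        assert list(cor.index) == ["ok"]

    def test_needs_three_samples(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            correlation_matrix(mat)


class TestSignedAdjacency:
    def test_endpoint_values(self):
        cor = pd.DataFrame([[1.0, 1.0, -1.0, 0.0],
                            [1.0, 1.0, 0.0, 0.0],
                            [-1.0, 0.0, 1.0, 0.0],
                            [0.0, 0.0, 0.0, 1.0]],
                           index=list("abcd"), columns=list("abcd"))
        adj = signed_adjacency(cor, beta=19)
        assert adj.loc["a", "b"] == pytest.approx(1.0)
        assert adj.loc["a", "c"] == pytest.approx(0.0)
        assert adj.loc["a", "d"] == pytest.approx(0.5**19)
        assert adj.loc["a", "d"] == pytest.approx(1.9073e-6, rel=1e-4)

    @given(st.floats(-0.999, 0.999), st.integers(1, 24))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_beta(self, r, beta):
        cor = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        low = signed_adjacency(cor, beta).loc["a", "b"]
        high = signed_adjacency(cor, beta + 1).loc["a", "b"]
        assert high <= low

    def test_bad_beta(self):
        cor = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            signed_adjacency(cor, beta=0)


class TestScaleFreeFit:
    def test_power_law_degrees_fit_well(self, rng):
        # discrete power law p(k) ~ k^-2 over k = 1..100
        ks = np.arange(1, 101, dtype=float)
        weights = ks**-2.0
        k = rng.choice(ks, size=5000, p=weights / weights.sum())
        fit = scale_free_fit(k)
        assert fit.fit_index >= 0.95
        assert fit.slope < 0

    def test_constant_degrees_degenerate(self):
        with pytest.raises(DegenerateDegreeDistribution):
            scale_free_fit(np.full(100, 3.0))

    def test_near_uniform_connectivity_fits_poorly(self, rng):
        # one tight all-to-all module: every gene has nearly the same k
        cfg = SimulationConfig(seed=1, modules=(ModuleSpec(80, (0.95, 0.99)),),
                               n_noise_genes=0, noise_sd=0.1)
        mat, _, _ = simulate_modular_expression(cfg)
        adj = signed_adjacency(correlation_matrix(log_transform(mat)), 6)
        a = adj.to_numpy().copy()
        np.fill_diagonal(a, 0.0)
        fit = scale_free_fit(a.sum(axis=1))
        assert fit.fit_index < 0.5


@pytest.fixture(scope="module")
def benchmark_logmat():
    mat, _, _ = simulate_modular_expression(SimulationConfig(seed=1))
    return log_transform(mat)


class TestPickSoftThreshold:
    def test_choice_consistent_with_fit_table(self, benchmark_logmat):
        res = pick_soft_threshold(benchmark_logmat)
        qualifying = res.fits[res.fits["fit_index"] >= 0.8]["power"]
        if res.reached_cut:
            assert res.beta == int(qualifying.iloc[0])
        else:
            assert qualifying.empty
            assert res.beta in list(res.fits["power"])

    def test_trivial_cut_returns_first_qualifying_power(self, benchmark_logmat):
        res = pick_soft_threshold(benchmark_logmat, fit_cut=-1.0)
        assert res.beta == 1 and res.reached_cut

    def test_unreachable_cut_sets_fallback_flag(self, benchmark_logmat):
        res = pick_soft_threshold(benchmark_logmat, fit_cut=1.01)
        assert not res.reached_cut
        assert res.beta in list(res.fits["power"])

    def test_bad_powers(self, benchmark_logmat):
        with pytest.raises(ValueError):
            pick_soft_threshold(benchmark_logmat, powers=[3, 2, 1])


class TestTOM:
    def test_two_gene_reduction(self):
        idx = pd.Index(["a", "b"])
        adj = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=idx, columns=idx)
        tom = topological_overlap(adj)
        # L = 0, min k = a_12, denominator = a_12 + 1 - a_12 = 1
        assert tom.loc["a", "b"] == pytest.approx(0.3, abs=1e-15)

    def test_complete_graph(self):
        idx = pd.Index(list("abcd"))
        adj = pd.DataFrame(np.ones((4, 4)), index=idx, columns=idx)
        assert np.allclose(topological_overlap(adj).to_numpy(), 1.0)

    def test_matches_brute_force(self, rng):
        adj = random_adjacency(rng, 6)
        tom = topological_overlap(adj)
        assert np.allclose(tom.to_numpy(), brute_force_tom(adj.to_numpy()),
                           atol=1e-12)

    def test_range_and_symmetry(self, rng):
        for n in (5, 8, 10):
            tom = topological_overlap(random_adjacency(rng, n)).to_numpy()
            assert np.allclose(tom, tom.T, atol=1e-12)
            assert tom.min() >= 0.0 and tom.max() <= 1.0
            assert np.allclose(np.diag(tom), 1.0)


class TestDissTom:
    def test_conservation(self, rng):
        tom = topological_overlap(random_adjacency(rng, 7))
        diss = diss_tom(tom)
        off = ~np.eye(7, dtype=bool)
        assert np.allclose((diss.to_numpy() + tom.to_numpy())[off], 1.0)
        assert np.allclose(np.diag(diss.to_numpy()), 0.0)


class TestConnectivity:
    def test_three_gene_uniform(self):
        idx = pd.Index(list("abc"))
        adj = pd.DataFrame(0.5, index=idx, columns=idx)
        np.fill_diagonal(adj.values, 1.0)
        k = connectivity(adj)["k"]
        assert np.allclose(k, 1.0)

    def test_singleton_module_zero_kim(self):
        idx = pd.Index(list("abc"))
        adj = pd.DataFrame(0.5, index=idx, columns=idx)
        assignment = pd.Series(["M1", "M1", "M2"], index=idx)
        conn = connectivity(adj, assignment)
        assert conn.loc["c", "kIM"] == 0.0
        assert conn.loc["a", "kIM"] == 0.5

    def test_matches_brute_force_two_modules(self, rng):
        adj = random_adjacency(rng, 8)
        assignment = pd.Series(["M1"] * 5 + ["M2"] * 3, index=adj.index)
        conn = connectivity(adj, assignment)
        a = adj.to_numpy()
        for i, g in enumerate(adj.index):
            k = sum(a[i, j] for j in range(8) if j != i)
            kim = sum(a[i, j] for j in range(8)
                      if j != i and assignment.iloc[j] == assignment.iloc[i])
            assert conn.loc[g, "k"] == pytest.approx(k, abs=1e-12)
            assert conn.loc[g, "kIM"] == pytest.approx(kim, abs=1e-12)


class TestScaledDegree:
    def test_dominant_gene_scores_one(self):
        idx = pd.Index(list("abcd"))
        kim = pd.Series([4.0, 2.0, 2.0, 7.0], index=idx)
        assignment = pd.Series(["M1", "M1", "M1", "M2"], index=idx)
        scaled = scaled_intramodular_degree(kim, assignment)
        assert scaled["a"] == 1.0
        assert scaled["b"] == pytest.approx(0.5)
        assert scaled["d"] == 1.0

    def test_equal_kim_all_one(self):
        idx = pd.Index(list("abc"))
        scaled = scaled_intramodular_degree(
            pd.Series(2.0, index=idx), pd.Series("M1", index=idx))
        assert (scaled == 1.0).all()

    def test_zero_module_scores_zero(self):
        idx = pd.Index(list("ab"))
        scaled = scaled_intramodular_degree(
            pd.Series(0.0, index=idx), pd.Series("M1", index=idx))
        assert (scaled == 0.0).all()


class TestLogBaseInvariance:
    def test_adjacency_and_tom_identical_for_log2_vs_ln(self, rng):
        mat = pd.DataFrame(rng.gamma(2.0, 5.0, size=(20, 10)),
                           index=[f"g{i}" for i in range(20)],
                           columns=[f"s{j}" for j in range(10)])
        adj2 = signed_adjacency(correlation_matrix(log_transform(mat, 2.0)), 7)
        adje = signed_adjacency(correlation_matrix(log_transform(mat, np.e)), 7)
        assert np.allclose(adj2.to_numpy(), adje.to_numpy(), atol=1e-10)
        tom2 = topological_overlap(adj2)
        tome = topological_overlap(adje)
        assert np.allclose(tom2.to_numpy(), tome.to_numpy(), atol=1e-10)
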