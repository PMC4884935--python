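"""Correlation matrices, thresholding, connectivity and power-law fits."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coexmod import (
    CorrelationMatrix,
    SyntheticConfig,
    build_network,
    connectivity,
    fit_discrete_powerlaw,
    generate_expression,
    pearson_matrix,
    sample_discrete_powerlaw,
    scalefree_test,
    select_threshold,
)
from conftest import make_table


def corr_from_array(arr, genes=None) -> CorrelationMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=genes, columns=genes)
    counts = pd.DataFrame(10, index=genes, columns=genes)
    return CorrelationMatrix(r=df, n_shared=counts)


class TestPearsonMatrix:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        table = make_table(np.vstack([x, -x]))
        corr = pearson_matrix(table)
        assert corr.r.iloc[0, 0] == 1.0
        assert corr.r.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula_on_complete_pairs(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(8, 12))
        corr = pearson_matrix(make_table(vals))
        for i, j in itertools.combinations(range(8), 2):
            a, b = vals[i], vals[j]
            expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
                np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
            )
            assert corr.r.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_noise_pairs_mean_r_near_zero(self):
        # 1,000 independent gene pairs at n=10: mean r within +-0.05
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(2000, 10))
        table = make_table(vals)
        x = vals - vals.mean(axis=1, keepdims=True)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        rs = np.einsum("ij,ij->i", x[:1000], x[1000:])
        assert abs(np.mean(rs)) < 0.05

    def test_too_few_shared_samples_undefined(self):
        vals = np.full((2, 10), np.nan)
        vals[0, :5] = [1, 2, 3, 4, 5]
        vals[1, :5] = [2, 3, 4, 5, 7]
        table = make_table(vals)
        corr = pearson_matrix(table, min_shared=6)
        assert np.isnan(corr.r.iloc[0, 1])
        assert corr.n_shared.iloc[0, 1] == 5
        # undefined pairs never create edges
        assert build_network(corr, 0.1).n_edges == 0

    def test_requires_three_samples(self):
        table = make_table(np.ones((2, 4)))
        with pytest.raises(ValueError, match="fewer than 3"):
            pearson_matrix(table, group="CT")


class TestBuildNetwork:
    def test_noise_matrix_at_tau_one_is_empty(self):
        rng = np.random.default_rng(3)
        corr = corr_from_array(np.clip(rng.uniform(-0.5, 0.5, (5, 5)), -1, 1))
        assert build_network(corr, 1.0).n_edges == 0

    def test_triangle(self):
        arr = np.full((3, 3), 0.99)
        np.fill_diagonal(arr, 1.0)
        net = build_network(corr_from_array(arr), 0.97)
        assert net.n_nodes == 3 and net.n_edges == 3

    def test_two_planted_blocks_give_disconnected_cliques(self):
        arr = np.full((6, 6), 0.2)
        arr[:3, :3] = 0.9
        arr[3:, 3:] = 0.9
        np.fill_diagonal(arr, 1.0)
        net = build_network(corr_from_array(arr), 0.5)
        comps = list(nx.connected_components(net.graph))
        assert sorted(len(c) for c in comps) == [3, 3]

    def test_negative_correlations_kept_with_sign(self):
        arr = np.array([[1.0, -0.95], [-0.95, 1.0]])
        net = build_network(corr_from_array(arr), 0.9)
        assert net.n_edges == 1
        (_, _, d), = net.graph.edges(data=True)
        assert d["sign"] == -1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotone(self, seed):
        rng = np.random.default_rng(seed)
        arr = np.clip(rng.uniform(-1, 1, size=(12, 12)), -1, 1)
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 1.0)
        corr = corr_from_array(arr)
        t1, t2 = sorted(rng.uniform(0.1, 0.95, size=2))
        e_low = set(map(frozenset, build_network(corr, t1).graph.edges()))
        e_high = set(map(frozenset, build_network(corr, t2).graph.edges()))
        assert e_high <= e_low


class TestSelectThreshold:
    def test_fully_connected_structure_returns_largest(self):
        arr = np.full((6, 6), 0.99)
        np.fill_diagonal(arr, 1.0)
        corr = corr_from_array(arr)
        tau = select_threshold(corr, [0.90, 0.95, 0.98], stability_delta=0.005)
        assert tau == 0.98

    def test_grid_above_max_abs_r_errors(self):
        arr = np.full((4, 4), 0.3)
        np.fill_diagonal(arr, 1.0)
        with pytest.raises(ValueError, match="diagnostics"):
            select_threshold(corr_from_array(arr), [0.8, 0.9])

    def test_selected_threshold_recovers_planted_modules(self):
        from sklearn.metrics import adjusted_rand_score
        from coexmod import louvain

        cfg = SyntheticConfig(n_genes=150, module_sizes=(50, 50, 50),
                              factor_strength=0.9, noise_sd=0.3, seed=2)
        table, truth = generate_expression(cfg)
        corr = pearson_matrix(table, group="CT")
        tau = select_threshold(corr, np.arange(0.5, 0.96, 0.05),
                               min_giant_fraction=0.3, seed=0)
        part = louvain(build_network(corr, tau), seed=0)
        shared = [g for g in part.labels if g in truth.module_of]
        ari = adjusted_rand_score(
            [truth.module_of[g] for g in shared],
            [part.labels[g] for g in shared],
        )
        assert ari >= 0.9


class TestConnectivity:
    @pytest.mark.parametrize(
        "n,l,expected",
        [(236, 908, 7.69), (300, 629, 4.19)],
    )
    def test_average_degree_two_decimals(self, n, l, expected):
        g = nx.gnm_random_graph(n, l, seed=0)
        assert round(connectivity(g), 2) == expected

    def test_edgeless_graph_zero(self):
        g = nx.empty_graph(10)
        assert connectivity(g) == 0.0

    def test_equals_mean_degree(self):
        g = nx.gnp_random_graph(50, 0.2, seed=1)
        mean_deg = np.mean([d for _, d in g.degree()])
        assert connectivity(g) == pytest.approx(mean_deg, abs=0)


class TestPowerLaw:
    def test_sampler_matches_target_distribution(self):
        rng = np.random.default_rng(4)
        x = sample_discrete_powerlaw(2.5, 1, 5000, rng)
        assert x.min() >= 1
        # P(X=1) = 1/zeta(2.5) ~ 0.745
        assert np.mean(x == 1) == pytest.approx(0.745, abs=0.03)

    def test_constant_degrees_flagged_degenerate(self):
        fit = fit_discrete_powerlaw([4] * 100)
        assert fit.degenerate

    def test_regular_graph_not_scale_free(self):
        fit = scalefree_test(nx.cycle_graph(50))
        assert fit.degenerate

    def test_bootstrap_p_reported_for_er_graph(self):
        # Erdos-Renyi degrees are Poisson-like, not power law; the
        # bootstrap p is reported (logged), rejection not asserted.
        g = nx.gnp_random_graph(500, 8 / 500, seed=2)
        fit = scalefree_test(g, bootstrap_reps=20, seed=0)
        assert fit.p_value is not None and 0.0 <= fit.p_value <= 1.0
        print(f"ER bootstrap p = {fit.p_value}")
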