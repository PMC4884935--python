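"""Louvain partitions, modularity, mixing matrix and coarse graining."""

import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from coexmod import (
    SyntheticConfig,
    coarse_grain,
    community_subnetworks,
    connectivity,
    generate_expression,
    louvain,
    mixing_matrix,
    modularity,
    pearson_matrix,
    robustness_sweep,
)
from conftest import random_graph
from test_network import corr_from_array


def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


class TestModularity:
    def test_single_community_zero(self):
        g = nx.gnp_random_graph(20, 0.3, seed=0)
        labels = {n: "A" for n in g.nodes()}
        assert modularity(g, labels) == 0.0

    def test_two_triangles_correct_split(self):
        labels = {0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B"}
        assert modularity(two_triangles(), labels) == 0.5

    def test_matches_networkx_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            g = random_graph(rng, n_max=25)
            if g.number_of_edges() == 0:
                continue
            labels = {n: int(rng.integers(0, 4)) for n in g.nodes()}
            comms = [
                {n for n in g if labels[n] == c} for c in set(labels.values())
            ]
            comms = [c for c in comms if c]
            expected = nx.community.modularity(g, comms)
            assert modularity(g, labels) == pytest.approx(expected, abs=1e-12)

    def test_random_labels_on_er_graph_near_zero(self):
        g = nx.gnp_random_graph(500, 0.02, seed=3)
        rng = np.random.default_rng(3)
        labels = {n: int(rng.integers(0, 5)) for n in g.nodes()}
        assert abs(modularity(g, labels)) < 0.1

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(nx.empty_graph(5), {n: "A" for n in range(5)})

    def test_incomplete_labels_rejected(self):
        g = two_triangles()
        with pytest.raises(ValueError):
            modularity(g, {0: "A"})


class TestLouvain:
    def test_two_triangles_found_exactly(self):
        part = louvain(two_triangles(), seed=0)
        assert part.q == pytest.approx(0.5, abs=1e-12)
        assert len({part.labels[n] for n in (0, 1, 2)}) == 1
        assert len({part.labels[n] for n in (3, 4, 5)}) == 1
        assert part.labels[0] != part.labels[3]

    def test_complete_graph_single_community(self):
        part = louvain(nx.complete_graph(8), seed=0)
        assert part.n_communities == 1
        assert part.q == 0.0

    def test_reported_q_matches_direct_evaluation(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = random_graph(rng, n_max=40)
            if g.number_of_edges() == 0:
                continue
            part = louvain(g, seed=1)
            assert part.q == pytest.approx(modularity(g, part.labels), abs=1e-12)

    def test_q_beats_trivial_baselines(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            g = random_graph(rng, n_max=30)
            if g.number_of_edges() == 0:
                continue
            part = louvain(g, seed=0)
            single = modularity(g, {n: "A" for n in g.nodes()})
            singletons = modularity(g, {n: n for n in g.nodes()})
            assert part.q >= single - 1e-12
            assert part.q >= singletons - 1e-12

    def test_planted_partition_recovered(self):
        aris = []
        for seed in range(10):
            g = nx.planted_partition_graph(4, 25, 0.3, 0.01, seed=seed)
            planted = [n // 25 for n in g.nodes()]
            part = louvain(g, seed=seed)
            aris.append(
                adjusted_rand_score(planted, [part.labels[n] for n in g.nodes()])
            )
        assert np.mean(aris) >= 0.9

    def test_labels_sorted_by_size(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations(range(5), 2))  # clique of 5
        g.add_edges_from([(10, 11), (11, 12), (10, 12)])  # triangle
        g.add_edge(0, 10)
        part = louvain(g, seed=0)
        assert part.labels[0] == "A"  # largest community named A
        assert part.sizes["A"] == max(part.sizes.values())

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(60, 0.1, seed=7)
        p1 = louvain(g, seed=9)
        p2 = louvain(g, seed=9)
        assert p1.labels == p2.labels and p1.q == p2.q

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain(nx.Graph(), seed=0)


class TestMixingMatrix:
    def test_complete_bipartite_weight_one(self):
        g = nx.complete_bipartite_graph(2, 3)
        labels = {n: ("L" if n < 2 else "R") for n in g.nodes()}
        mm = mixing_matrix(g, labels)
        assert mm.e.loc["L", "R"] == 6
        assert mm.w.loc["L", "R"] == 1.0
        assert mm.check_conservation(g.number_of_edges())

    def test_disjoint_cliques_zero_between(self):
        g = two_triangles()
        labels = {n: ("A" if n < 3 else "B") for n in g.nodes()}
        mm = mixing_matrix(g, labels)
        assert mm.w.loc["A", "B"] == 0.0
        assert mm.e.loc["A", "A"] == 3 and mm.e.loc["B", "B"] == 3

    def test_edge_conservation_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            g = random_graph(rng)
            labels = {n: int(rng.integers(0, 4)) for n in g.nodes()}
            mm = mixing_matrix(g, labels)
            assert mm.check_conservation(g.number_of_edges())

    def test_node_strength_sums_off_diagonal(self):
        g = nx.gnp_random_graph(30, 0.2, seed=6)
        labels = {n: n % 3 for n in g.nodes()}
        mm = mixing_matrix(g, labels)
        for c in mm.sizes.index:
            expected = sum(mm.w.loc[c, b] for b in mm.sizes.index if b != c)
            assert mm.node_strength[c] == pytest.approx(expected, abs=1e-12)


class TestCoarseGrain:
    def test_single_community_single_node(self):
        g = nx.complete_graph(5)
        cgcs = coarse_grain(g, {n: "A" for n in g.nodes()})
        assert cgcs.number_of_nodes() == 1 and cgcs.number_of_edges() == 0
        assert cgcs.nodes["A"]["size"] == 5
        assert cgcs.nodes["A"]["within_density"] == 1.0

    def test_bipartite_contraction(self):
        g = nx.complete_bipartite_graph(2, 3)
        labels = {n: ("L" if n < 2 else "R") for n in g.nodes()}
        cgcs = coarse_grain(g, labels)
        assert cgcs.number_of_nodes() == 2 and cgcs.number_of_edges() == 1
        assert cgcs.edges["L", "R"]["weight"] == 1.0

    def test_hh_restriction(self):
        g = two_triangles()
        labels = {n: ("A" if n < 3 else "B") for n in g.nodes()}
        assert coarse_grain(g, labels, hh_genes=[]).number_of_nodes() == 0
        restricted = coarse_grain(g, labels, hh_genes=[0])
        assert list(restricted.nodes()) == ["A"]

    def test_node_count_equals_community_count(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_graph(rng)
            k = int(rng.integers(1, 5))
            labels = {n: int(rng.integers(0, k)) for n in g.nodes()}
            cgcs = coarse_grain(g, labels)
            assert cgcs.number_of_nodes() == len(set(labels.values()))


@pytest.fixture(scope="module")
def planted_corr():
    cfg = SyntheticConfig(n_genes=150, module_sizes=(50, 50, 50),
                          factor_strength=0.9, noise_sd=0.3, seed=0)
    table, truth = generate_expression(cfg)
    return pearson_matrix(table, group="CT"), truth


class TestRobustnessSweep:
    def test_partition_stable_across_taus(self, planted_corr):
        corr, _ = planted_corr
        sweep = robustness_sweep(corr, np.arange(0.5, 0.91, 0.1), seed=0,
                                 n_restarts=3)
        assert (~sweep["empty"]).all()
        assert (sweep["ari"] >= 0.9).all()

    def test_tau_above_max_flagged_empty(self, planted_corr):
        corr, _ = planted_corr
        sweep = robustness_sweep(corr, [0.5, 0.9999], seed=0, n_restarts=2)
        assert bool(sweep.loc[sweep["tau"] > 0.999, "empty"].iloc[0])

    def test_single_tau_self_ari_one(self, planted_corr):
        corr, _ = planted_corr
        sweep = robustness_sweep(corr, [0.7], seed=0, n_restarts=2)
        assert len(sweep) == 1 and sweep["ari"].iloc[0] == 1.0


class TestCommunitySubnetworks:
    def test_min_size_boundary(self):
        cfg = SyntheticConfig(n_genes=220, module_sizes=(100, 99),
                              factor_strength=0.9, noise_sd=0.3, seed=1)
        table, truth = generate_expression(cfg)
        labels = dict(truth.module_of)
        for g in table.values.index:
            labels.setdefault(g, "BG")
        out = community_subnetworks(table, labels, tau=0.7, min_size=100,
                                    group="CT")
        assert set(out["community"]) == {"M1"}  # 99-gene module excluded

    def test_connectivity_consistent_with_direct_computation(self):
        from coexmod import build_network

        cfg = SyntheticConfig(n_genes=120, module_sizes=(60, 60),
                              factor_strength=0.9, noise_sd=0.3, seed=2)
        table, truth = generate_expression(cfg)
        out = community_subnetworks(table, truth.module_of, tau=0.7,
                                    min_size=50, group="CT")
        for row in out.itertuples(index=False):
            genes = [g for g, m in truth.module_of.items() if m == row.community]
            sub = table.with_values(table.values.loc[genes])
            net = build_network(pearson_matrix(sub, group="CT"), 0.7)
            assert row.connectivity == connectivity(net)
            assert row.n_nodes == net.n_nodes and row.n_edges == net.n_edges
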