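import numpy as np
import pytest

from fcnet import (
    characteristic_path_length,
    clustering_coefficient,
    degree,
    modularity,
    modularity_q,
    random_benchmark,
    small_worldness,
    subject_metrics,
)
from fcnet.connectivity import BinaryNetwork
from fcnet.metrics import DisconnectedWarning, RandomBenchmark, _gnm_adjacency

from .conftest import complete_network, network_from_edges
from .oracles import (
    all_connected_atlas_graphs,
    max_modularity_exhaustive,
    modularity_of_blocks,
    pairwise_shortest_paths_bfs,
)


def star(n):
    return network_from_edges(n, [(0, i) for i in range(1, n)])


def path3():
    return network_from_edges(3, [(0, 1), (1, 2)])


def k4_minus_edge():
    return network_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])


def two_k4s():
    edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    edges += [(i + 4, j + 4) for i, j in edges]
    return network_from_edges(8, edges)


class TestDegreeAndClustering:
    def test_degree_examples(self):
        assert (degree(complete_network(4)) == 3).all()
        assert (degree(network_from_edges(3, [])) == 0).all()
        k = degree(star(5))
        assert k[0] == 4 and (k[1:] == 1).all()

    def test_clustering_examples(self):
        assert clustering_coefficient(complete_network(3))[0] == pytest.approx(1.0)
        assert clustering_coefficient(star(5))[0] == 0.0
        C, c_i = clustering_coefficient(k4_minus_edge())
        assert np.allclose(c_i, [2 / 3, 2 / 3, 1.0, 1.0])
        assert C == pytest.approx(5 / 6)


class TestPathLength:
    def test_complete_and_path(self):
        assert characteristic_path_length(complete_network(5))[0] == pytest.approx(1.0)
        L, l_i = characteristic_path_length(path3())
        assert L == pytest.approx(4 / 3)
        assert np.allclose(l_i, [1.5, 1.0, 1.5])

    def test_disconnected_counts_reachable_pairs_only(self):
        net = network_from_edges(4, [(0, 1), (2, 3)])
        with pytest.warns(DisconnectedWarning, match="8 unreachable"):
            L, _ = characteristic_path_length(net)
        assert L == pytest.approx(1.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            characteristic_path_length(network_from_edges(3, []))

    def test_agrees_with_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            net = _gnm_adjacency(rng, 12, int(rng.integers(6, 30)))
            d = pairwise_shortest_paths_bfs(net.adjacency)
            np.fill_diagonal(d, np.inf)
            finite = np.isfinite(d)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DisconnectedWarning)
                L, _ = characteristic_path_length(net)
            assert L == pytest.approx(d[finite].mean())


class TestRandomBenchmark:
    def test_complete_graph_benchmark_is_trivial(self):
        b = random_benchmark(complete_network(5), n_realizations=3, seed=0)
        assert b.L_r == pytest.approx(1.0)
        assert b.C_r == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        net = _gnm_adjacency(np.random.default_rng(1), 20, 40)
        a = random_benchmark(net, n_realizations=5, seed=9)
        b = random_benchmark(net, n_realizations=5, seed=9)
        assert (a.L_r, a.C_r) == (b.L_r, b.C_r)

    def test_clustering_of_uniform_graph_matches_density(self):
        net = _gnm_adjacency(np.random.default_rng(2), 110, 1199)
        b = random_benchmark(net, n_realizations=20, seed=5)
        assert b.C_r == pytest.approx(0.2, abs=0.02)


class TestSmallWorldness:
    def test_arithmetic(self):
        bench = RandomBenchmark(1, L_r=1.90, C_r=0.20, seed=0)
        gamma, lam, sigma = small_worldness(0.58, 2.20, bench)
        assert gamma == pytest.approx(2.90)
        assert lam == pytest.approx(2.20 / 1.90)
        assert sigma == pytest.approx(2.90 * 1.90 / 2.20)

    def test_sigma_identity_and_linearity(self):
        bench = RandomBenchmark(1, L_r=1.5, C_r=0.3, seed=0)
        g1, l1, s1 = small_worldness(0.4, 2.0, bench)
        assert s1 == g1 / l1
        _, _, s2 = small_worldness(0.8, 2.0, bench)
        assert s2 == pytest.approx(2 * s1)

    def test_zero_benchmark_rejected(self):
        with pytest.raises(ValueError):
            small_worldness(0.5, 2.0, RandomBenchmark(1, L_r=0.0, C_r=0.2, seed=0))

    def test_er_graphs_have_sigma_near_one(self):
        rng = np.random.default_rng(8)
        sigmas = []
        for _ in range(50):
            net = _gnm_adjacency(rng, 110, 1199)
            C, _ = clustering_coefficient(net)
            L, _ = characteristic_path_length(net)
            bench = random_benchmark(net, n_realizations=5, seed=int(rng.integers(2**31)))
            sigmas.append(small_worldness(C, L, bench)[2])
        assert 0.9 < np.mean(sigmas) < 1.1


class TestModularity:
    def test_single_community_clique_has_zero_q(self):
        net = complete_network(4)
        assert modularity_q(net, np.zeros(4, dtype=int)) == pytest.approx(0.0)

    def test_two_cliques_split_gives_half(self):
        net = two_k4s()
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert modularity_q(net, labels) == pytest.approx(0.5)
        assert max_modularity_exhaustive(net.adjacency.astype(float)) == pytest.approx(0.5)
        q, part = modularity(net, seed=1)
        assert q == pytest.approx(0.5)
        assert len(np.unique(part)) == 2

    def test_matches_direct_formula_and_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(6)
        for _ in range(5):
            net = _gnm_adjacency(rng, 10, 20)
            labels = rng.integers(0, 3, size=10)
            blocks = [list(np.flatnonzero(labels == c)) for c in np.unique(labels)]
            q_direct = modularity_of_blocks(net.adjacency.astype(float), blocks)
            assert modularity_q(net, labels) == pytest.approx(q_direct)
            g = nx.from_numpy_array(net.adjacency)
            q_nx = nx.community.modularity(g, [set(b) for b in blocks])
            assert modularity_q(net, labels) == pytest.approx(q_nx)

    def test_q_range_over_random_partitions(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            net = _gnm_adjacency(rng, 8, int(rng.integers(4, 20)))
            labels = rng.integers(0, 4, size=8)
            assert -0.5 <= modularity_q(net, labels) <= 1.0

    def test_louvain_never_beats_exhaustive_oracle(self):
        graphs = all_connected_atlas_graphs(max_nodes=6)
        rng = np.random.default_rng(9)
        picked = [graphs[i] for i in rng.choice(len(graphs), 25, replace=False)]
        for adj in picked:
            net = BinaryNetwork(adj, edge_density=0.0)
            q_best = max_modularity_exhaustive(adj.astype(float))
            q_louvain, _ = modularity(net, seed=2)
            assert q_louvain <= q_best + 1e-9
            assert q_louvain >= 0.9 * q_best - 1e-9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(network_from_edges(3, []), seed=0)


class TestSubjectMetrics:
    def test_complete_graph_bundle(self):
        sm = subject_metrics(complete_network(6), n_realizations=2, seed=0)
        assert sm.L == sm.C == sm.gamma == sm.lambda_ == sm.sigma == 1.0
        assert sm.Q == pytest.approx(0.0)

    def test_reproducible(self):
        net = _gnm_adjacency(np.random.default_rng(5), 30, 90)
        a = subject_metrics(net, n_realizations=4, seed=3)
        b = subject_metrics(net, n_realizations=4, seed=3)
        assert (a.L, a.C, a.sigma, a.Q) == (b.L, b.C, b.sigma, b.Q)

    def test_modular_network_is_small_world(self):
        # two dense 20-cliques connected by a couple of bridges
        edges = [(i, j) for i in range(20) for j in range(i + 1, 20)]
        edges += [(i + 20, j + 20) for i, j in edges]
        edges += [(0, 20), (5, 25)]
        net = network_from_edges(40, edges)
        sm = subject_metrics(net, n_realizations=10, seed=4)
        assert sm.sigma > 1.0
        assert sm.sigma == pytest.approx(sm.gamma / sm.lambda_)
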