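"""Topological measures for binary networks.

Global measures: characteristic path length L (mean shortest-path length
over reachable ordered pairs), mean clustering coefficient C, modularity Q
(Newman definition, Louvain-optimized), and the benchmark-normalized ratios
gamma = C/C_r, lambda = L/L_r and small-worldness sigma = gamma/lambda,
where the benchmark is the mean over uniform random graphs with the same
number of nodes and edges.  Node-wise measures: degree k_i, local clustering
C_i, local path length L_i, and a node-wise sigma_i = C_i*L_r/(C_r*L_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import BinaryNetwork

__all__ = [
    "SubjectGraphMetrics",
    "RandomBenchmark",
    "DisconnectedWarning",
    "degree",
    "clustering_coefficient",
    "characteristic_path_length",
    "random_benchmark",
    "small_worldness",
    "modularity_q",
    "modularity",
    "subject_metrics",
]


class DisconnectedWarning(UserWarning):
    """Some node pairs are unreachable and were excluded from L."""


@dataclass
class RandomBenchmark:
    """Mean path length and clustering of same-size uniform random graphs."""

    n_realizations: int
    L_r: float
    C_r: float
    seed: int


@dataclass
class SubjectGraphMetrics:
    """Global and node-wise topology of one subject's binary network."""

    subject_id: str
    L: float
    C: float
    gamma: float
    lambda_: float
    sigma: float
    Q: float
    degree: np.ndarray
    local_clustering: np.ndarray
    local_path_length: np.ndarray
    local_sigma: np.ndarray
    benchmark: RandomBenchmark
    partition: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def degree(net: BinaryNetwork) -> np.ndarray:
    """Number of neighbors of each node."""
    return net.adjacency.sum(axis=1).astype(int)


def clustering_coefficient(net: BinaryNetwork) -> tuple[float, np.ndarray]:
    """(mean clustering C, per-node C_i); C_i = 0 when degree < 2."""
    a = net.adjacency.astype(np.int64)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2  # closed neighbor pairs per node
    pairs = k * (k - 1) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        c_i = np.where(pairs > 0, triangles / pairs, 0.0)
    return float(c_i.mean()), c_i


def characteristic_path_length(net: BinaryNetwork) -> tuple[float, np.ndarray]:
    """(L, per-node L_i) from breadth-first shortest paths.

    L averages over all ordered reachable pairs; L_i averages distances from
    node i to the nodes reachable from it (NaN for isolated nodes).
    Unreachable pairs are excluded with a :class:`DisconnectedWarning`
    stating how many were dropped.
    """
    if net.n_edges == 0:
        raise ValueError("characteristic path length is undefined for an empty graph")
    d = shortest_path(csr_matrix(net.adjacency), method="D", unweighted=True)
    np.fill_diagonal(d, np.inf)  # exclude self-pairs from both L and L_i
    finite = np.isfinite(d)
    n = net.n_nodes
    n_excluded = n * (n - 1) - int(finite.sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} unreachable ordered node pairs excluded from L",
            DisconnectedWarning,
            stacklevel=2,
        )
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        l_i = np.where(counts > 0, sums / counts, np.nan)
    L = float(sums.sum() / finite.sum())
    return L, l_i


def _gnm_adjacency(rng: np.random.Generator, n: int, m: int) -> BinaryNetwork:
    """Uniform random graph with n nodes and exactly m edges."""
    iu, ju = np.triu_indices(n, 1)
    pick = rng.choice(iu.size, size=m, replace=False)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[pick], ju[pick]] = 1
    adj[ju[pick], iu[pick]] = 1
    return BinaryNetwork(adj, edge_density=2 * m / (n * (n - 1)))


def random_benchmark(
    net: BinaryNetwork, n_realizations: int = 100, seed: int = 0
) -> RandomBenchmark:
    """L_r and C_r averaged over uniform random graphs with the same n, m."""
    if net.n_edges == 0:
        raise ValueError("benchmark requires at least one edge")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rng = np.random.default_rng(seed)
    n, m = net.n_nodes, net.n_edges
    ls, cs = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedWarning)
        for _ in range(n_realizations):
            g = _gnm_adjacency(rng, n, m)
            ls.append(characteristic_path_length(g)[0])
            cs.append(clustering_coefficient(g)[0])
    return RandomBenchmark(n_realizations, float(np.mean(ls)), float(np.mean(cs)), seed)


def small_worldness(
    C: float, L: float, benchmark: RandomBenchmark
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) = (C/C_r, L/L_r, gamma/lambda)."""
    if benchmark.C_r <= 0 or benchmark.L_r <= 0:
        raise ValueError("benchmark C_r and L_r must be positive")
    gamma = C / benchmark.C_r
    lam = L / benchmark.L_r
    return gamma, lam, gamma / lam


def modularity_q(net: BinaryNetwork, partition: np.ndarray | dict) -> float:
    """Newman modularity of a given partition.

    Q = sum_c [ e_c/m - (d_c/2m)^2 ] where e_c counts intra-community edges,
    d_c is the total degree inside community c and m the total edge count.
    """
    if net.n_edges == 0:
        raise ValueError("modularity is undefined for an empty graph")
    n = net.n_nodes
    if isinstance(partition, dict):
        labels = np.array([partition[i] for i in range(n)])
    else:
        labels = np.asarray(partition)
        if labels.shape != (n,):
            raise ValueError("partition must assign a community to every node")
    a = net.adjacency.astype(np.int64)
    m = net.n_edges
    k = a.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = a[np.ix_(mask, mask)].sum() / 2
        d_c = k[mask].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def modularity(
    net: BinaryNetwork, seed: int = 0, n_restarts: int = 8
) -> tuple[float, np.ndarray]:
    """(Q, partition) maximized by the Louvain heuristic.

    The heuristic is run ``n_restarts`` times with seeds derived
    deterministically from ``seed`` and the best-Q partition is kept, which
    removes most of the single-run variability of Louvain on small graphs.
    """
    if net.n_edges == 0:
        raise ValueError("modularity is undefined for an empty graph")
    g = nx.from_numpy_array(net.adjacency)
    restart_seeds = np.random.SeedSequence([seed, 2]).generate_state(n_restarts)
    best_q, best_labels = -np.inf, None
    for s in restart_seeds:
        communities = nx.community.louvain_communities(g, seed=int(s & 0x7FFFFFFF))
        labels = np.empty(net.n_nodes, dtype=int)
        for c, members in enumerate(communities):
            for node in members:
                labels[node] = c
        q = modularity_q(net, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def subject_metrics(
    net: BinaryNetwork, n_realizations: int = 100, seed: int = 0
) -> SubjectGraphMetrics:
    """Bundle all global and node-wise measures for one subject's network."""
    k = degree(net)
    C, c_i = clustering_coefficient(net)
    L, l_i = characteristic_path_length(net)
    bench = random_benchmark(net, n_realizations=n_realizations, seed=seed)
    gamma, lam, sigma = small_worldness(C, L, bench)
    Q, partition = modularity(net, seed=seed)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_i = np.where(l_i > 0, c_i * bench.L_r / (bench.C_r * l_i), np.nan)
    return SubjectGraphMetrics(
        subject_id=net.subject_id,
        L=L,
        C=C,
        gamma=gamma,
        lambda_=lam,
        sigma=sigma,
        Q=Q,
        degree=k,
        local_clustering=c_i,
        local_path_length=l_i,
        local_sigma=sigma_i,
        benchmark=bench,
        partition=partition,
    )
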