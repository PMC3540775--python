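"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive set
partitions for modularity, a literal step-up loop for FDR, and direct
formula evaluation for Newman's Q.
"""

from __future__ import annotations

import numpy as np


def set_partitions(items: list[int]):
    """All partitions of ``items`` into nonempty blocks (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1 :]
        yield [[first]] + partition


def modularity_of_blocks(adj: np.ndarray, blocks: list[list[int]]) -> float:
    """Newman Q evaluated directly from the block list."""
    m = adj.sum() / 2
    k = adj.sum(axis=1)
    q = 0.0
    for block in blocks:
        idx = np.asarray(block)
        e_c = adj[np.ix_(idx, idx)].sum() / 2
        d_c = k[idx].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def max_modularity_exhaustive(adj: np.ndarray) -> float:
    """True maximum Q over every partition (feasible for <= ~8 nodes)."""
    n = adj.shape[0]
    return max(
        modularity_of_blocks(adj, blocks) for blocks in set_partitions(list(range(n)))
    )


def bh_stepup_bruteforce(p: np.ndarray, q_level: float = 0.05):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= q_level


def pairwise_shortest_paths_bfs(adj: np.ndarray) -> np.ndarray:
    """Plain BFS distances, np.inf where unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def all_connected_atlas_graphs(max_nodes: int = 6):
    """Connected graphs with 3..max_nodes nodes from the networkx atlas."""
    import networkx as nx

    out = []
    for g in nx.graph_atlas_g():
        n = g.number_of_nodes()
        if 3 <= n <= max_nodes and g.number_of_edges() > 0 and nx.is_connected(g):
            out.append(nx.to_numpy_array(g, dtype=np.int8))
    return out
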