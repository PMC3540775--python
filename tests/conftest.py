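import numpy as np
import pytest

from fcnet import GeneratorConfig, make_node_table
from fcnet.connectivity import BinaryNetwork


def network_from_edges(n: int, edges) -> BinaryNetwork:
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    m = len(set(map(tuple, (sorted(e) for e in edges))))
    density = 2 * m / (n * (n - 1)) if n > 1 else 0.0
    return BinaryNetwork(adj, edge_density=density)


def complete_network(n: int) -> BinaryNetwork:
    return network_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A 20-node cohort small enough for fast unit tests."""
    return GeneratorConfig(
        n_nodes=20,
        n_volumes=64,
        n_modules=4,
        n_controls=5,
        n_cases=5,
        random_seed=11,
    )


@pytest.fixture(scope="session")
def default_node_table():
    return make_node_table(GeneratorConfig())
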