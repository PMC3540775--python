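"""Connection reach, hub ranking and seed-region profiling.

The Euclidean distance (ED) between centroids of connected regions
approximates the physical reach of a connection; a node's mean neighbor ED
summarizes how far its functional partners lie.  Hubs are the highest-degree
nodes of each subject's network; their cross-subject frequency per group
exposes shifts in the network core.  The seed profile characterizes one
chosen region's connections across subjects, separating group-specific
partners from shared ones, the latter compared by a pooled two-proportion
z-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import BinaryNetwork

__all__ = [
    "neighbor_mean_distance",
    "top_hubs",
    "hub_frequency",
    "seed_profile",
    "seed_frequency_z",
    "SeedConnectivityProfile",
]


def _centroids(node_table: pd.DataFrame) -> np.ndarray:
    return node_table[["x_mm", "y_mm", "z_mm"]].to_numpy(float)


def neighbor_mean_distance(
    net: BinaryNetwork, node_table: pd.DataFrame
) -> pd.DataFrame:
    """Mean ED (mm) from each node to its connected neighbors.

    Returns a frame with columns node_id, mean_neighbor_distance,
    defined_flag; isolated nodes get NaN with defined_flag False.
    """
    if len(node_table) != net.n_nodes:
        raise ValueError(
            f"node table has {len(node_table)} rows, network has {net.n_nodes} nodes"
        )
    xyz = _centroids(node_table)
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    a = net.adjacency.astype(float)
    k = a.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(k > 0, (a * dist).sum(axis=1) / k, np.nan)
    return pd.DataFrame(
        {
            "node_id": np.arange(net.n_nodes),
            "mean_neighbor_distance": mean_d,
            "defined_flag": k > 0,
        }
    )


def top_hubs(k: np.ndarray, hub_set_size: int = 15) -> np.ndarray:
    """Node ids of the ``hub_set_size`` highest-degree nodes.

    Sorted by degree descending; ties broken by ascending node id.
    """
    k = np.asarray(k)
    if hub_set_size > k.size:
        raise ValueError("hub_set_size exceeds the number of nodes")
    order = np.lexsort((np.arange(k.size), -k))
    return order[:hub_set_size]


def hub_frequency(
    degrees: dict[str, np.ndarray] | pd.DataFrame,
    groups: dict[str, str],
    hub_set_size: int = 15,
) -> pd.DataFrame:
    """Fraction of subjects per group in which each node is a top hub.

    ``degrees`` maps subject_id -> per-node degree vector (or a DataFrame
    with subjects as columns); ``groups`` maps subject_id -> group label.
    Returns node x group fractions; each subject contributes exactly
    ``hub_set_size`` hub memberships, so each group's column sums to
    ``hub_set_size``.
    """
    if isinstance(degrees, pd.DataFrame):
        degrees = {c: degrees[c].to_numpy() for c in degrees.columns}
    labels = sorted(set(groups.values()))
    n_nodes = len(next(iter(degrees.values())))
    counts = {g: np.zeros(n_nodes) for g in labels}
    sizes = {g: 0 for g in labels}
    for sid, k in degrees.items():
        g = groups[sid]
        sizes[g] += 1
        counts[g][top_hubs(np.asarray(k), hub_set_size)] += 1
    if any(sizes[g] == 0 for g in labels):
        raise ValueError("every group needs at least one subject")
    out = pd.DataFrame({g: counts[g] / sizes[g] for g in labels})
    out.insert(0, "node_id", np.arange(n_nodes))
    return out


@dataclass
class SeedConnectivityProfile:
    """Cross-subject connection profile of one seed region."""

    seed_node_id: int
    table: pd.DataFrame  # node_id, count/fraction per group, shared, z, significant
    group_specific_nodes: dict[str, list[int]] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)


def seed_frequency_z(x1: int, n1: int, x2: int, n2: int) -> float:
    """Pooled two-proportion z for seed-connection frequencies.

    z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* the pooled
    proportion; NaN when the pooled proportion is 0 or 1.
    """
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return math.nan
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return (p1 - p2) / se


def seed_profile(
    networks: list[BinaryNetwork],
    groups: dict[str, str],
    seed_node_id: int,
    attribution_threshold: float | None = None,
    z_threshold: float = 2.0,
) -> SeedConnectivityProfile:
    """Profile the seed region's connections across subjects and groups.

    A seed-partner connection is *attributed* to a group when its
    within-group frequency reaches ``attribution_threshold`` (default
    1/group size, i.e. at least one subject); it is *group-specific* when
    attributed in one group and present in zero subjects of the other.
    Partners present in both groups are compared by the pooled
    two-proportion z-score; |z| > ``z_threshold`` flags a significant
    frequency difference.  Partners absent everywhere are not reported.
    """
    n_nodes = networks[0].n_nodes
    if not 0 <= seed_node_id < n_nodes:
        raise ValueError(f"seed node {seed_node_id} out of range [0, {n_nodes})")
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"seed profile needs exactly 2 groups, got {labels}")
    g1, g2 = labels
    counts = {g: np.zeros(n_nodes, dtype=int) for g in labels}
    sizes = {g: 0 for g in labels}
    for net in networks:
        g = groups[net.subject_id]
        sizes[g] += 1
        counts[g] += net.adjacency[seed_node_id].astype(int)
    thresholds = {
        g: (attribution_threshold if attribution_threshold is not None else 1.0 / sizes[g])
        for g in labels
    }

    rows = []
    specific: dict[str, list[int]] = {g: [] for g in labels}
    for node in range(n_nodes):
        if node == seed_node_id:
            continue
        x1, x2 = int(counts[g1][node]), int(counts[g2][node])
        if x1 == 0 and x2 == 0:
            continue
        f1, f2 = x1 / sizes[g1], x2 / sizes[g2]
        attributed = {g1: f1 >= thresholds[g1], g2: f2 >= thresholds[g2]}
        shared = x1 > 0 and x2 > 0
        if attributed[g1] and x2 == 0:
            specific[g1].append(node)
        if attributed[g2] and x1 == 0:
            specific[g2].append(node)
        z = seed_frequency_z(x1, sizes[g1], x2, sizes[g2]) if shared else math.nan
        rows.append(
            {
                "node_id": node,
                f"count_{g1}": x1,
                f"count_{g2}": x2,
                f"fraction_{g1}": f1,
                f"fraction_{g2}": f2,
                "shared": shared,
                "z": z,
                "significant": bool(abs(z) > z_threshold) if math.isfinite(z) else False,
            }
        )
    table = pd.DataFrame(rows)
    return SeedConnectivityProfile(
        seed_node_id=seed_node_id,
        table=table,
        group_specific_nodes=specific,
        group_sizes=sizes,
    )
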