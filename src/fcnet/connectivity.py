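"""From regional time series to correlation matrices and binary networks.

The processing order is fixed: row demeaning, global-signal removal
(subtraction of the across-node mean time course), Pearson correlation, then
either zeroing of negative entries or proportional thresholding at a fixed
edge density followed by binarization.  Proportional thresholding keeps the
top fraction of positive correlations so every subject's network has the
same number of edges, which is what makes topological measures comparable
across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "ThresholdWarning",
    "demean",
    "remove_global_signal",
    "correlation_matrix",
    "zero_negatives",
    "threshold_by_density",
    "grand_mean",
    "retained_correlation_summary",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edge_list",
]


class ThresholdWarning(UserWarning):
    """Fewer positive correlations than requested edges."""


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region correlation matrix.

    The diagonal is stored as 1 but excluded from every summary statistic.
    ``variant`` is one of ``raw``, ``nonnegative``, ``thresholded``.
    """

    values: np.ndarray
    variant: str = "raw"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency at a fixed edge density."""

    adjacency: np.ndarray
    edge_density: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def _check_finite(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D region x time matrix")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    return series


def demean(series: np.ndarray) -> np.ndarray:
    """Subtract each region's temporal mean; every row mean becomes 0."""
    series = _check_finite(series)
    if series.shape[1] < 2:
        raise ValueError("need at least 2 volumes to demean")
    return series - series.mean(axis=1, keepdims=True)


def remove_global_signal(series: np.ndarray) -> np.ndarray:
    """Subtract the across-node mean time course from every node.

    After removal each volume (column) has mean exactly 0 across nodes.
    """
    series = _check_finite(series)
    if series.shape[0] < 2:
        raise ValueError("global signal removal needs at least 2 nodes")
    return series - series.mean(axis=0, keepdims=True)


def correlation_matrix(series: np.ndarray, subject_id: str = "") -> ConnectivityMatrix:
    """Pearson correlation of every pair of rows (variant ``raw``)."""
    series = _check_finite(series)
    if series.shape[1] < 3:
        raise ValueError("need at least 3 volumes for a correlation matrix")
    sd = series.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance time series at node(s) {zero.tolist()}"
            + (f" for subject {subject_id}" if subject_id else "")
        )
    r = np.corrcoef(series)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, variant="raw", subject_id=subject_id)


def zero_negatives(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Replace negative off-diagonal correlations by zero."""
    if cm.variant != "raw":
        raise ValueError(f"zero_negatives expects a raw matrix, got {cm.variant!r}")
    v = cm.values.copy()
    v[v < 0] = 0.0
    np.fill_diagonal(v, 1.0)
    return ConnectivityMatrix(v, variant="nonnegative", subject_id=cm.subject_id)


def _ranked_upper_pairs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle entries ordered by value descending, ties by (i, j)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = values[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def _select_edges(
    cm: ConnectivityMatrix, density: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    if cm.variant not in ("raw", "nonnegative"):
        raise ValueError(f"cannot threshold a {cm.variant!r} matrix")
    i, j, v = _ranked_upper_pairs(cm.values)
    n_pairs = v.size
    n_requested = int(np.floor(density * n_pairs))
    n_positive = int(np.count_nonzero(v > 0))
    if n_positive < n_requested:
        warnings.warn(
            f"only {n_positive} strictly positive correlations available for "
            f"{n_requested} requested edges; retaining all positive values"
            + (f" (subject {cm.subject_id})" if cm.subject_id else ""),
            ThresholdWarning,
            stacklevel=3,
        )
    n_keep = min(n_requested, n_positive)
    return i[:n_keep], j[:n_keep], v[:n_keep]


def threshold_by_density(cm: ConnectivityMatrix, density: float = 0.20) -> BinaryNetwork:
    """Binarize by keeping the top ``floor(density * n_pairs)`` correlations.

    Only strictly positive correlations are eligible; ties at the cutoff are
    broken deterministically by ascending (i, j) node index.  The realized
    edge density can fall below the request when too few correlations are
    positive (a :class:`ThresholdWarning` is emitted).
    """
    i, j, _ = _select_edges(cm, density)
    n = cm.n_nodes
    adj = np.zeros((n, n), dtype=np.int8)
    adj[i, j] = 1
    adj[j, i] = 1
    realized = 2.0 * i.size / (n * (n - 1))
    return BinaryNetwork(adj, edge_density=realized, subject_id=cm.subject_id)


def grand_mean(cm: ConnectivityMatrix) -> float:
    """Mean of the n(n-1)/2 off-diagonal upper-triangle entries."""
    iu, ju = np.triu_indices(cm.n_nodes, 1)
    return float(cm.values[iu, ju].mean())


def retained_correlation_summary(
    cm: ConnectivityMatrix, density: float = 0.20
) -> tuple[float, float]:
    """(smallest retained correlation, mean of retained correlations).

    The first element is the effective correlation threshold implied by the
    density; the second is the grand mean over the thresholded matrix,
    computed over retained entries only.
    """
    _, _, v = _select_edges(cm, density)
    if v.size == 0:
        raise ValueError("no positive correlations to retain")
    return float(v[-1]), float(v.mean())


# ---------------------------------------------------------------------------
# Matrix and edge-list I/O (square TSV with node_id header row/column)
# ---------------------------------------------------------------------------

def write_matrix_tsv(cm: ConnectivityMatrix, path: str | Path) -> None:
    n = cm.n_nodes
    df = pd.DataFrame(cm.values, index=range(n), columns=range(n))
    df.to_csv(path, sep="\t", index_label="node_id", float_format="%.10g")


def read_matrix_tsv(path: str | Path, variant: str = "raw", subject_id: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="node_id")
    return ConnectivityMatrix(df.to_numpy(float), variant=variant, subject_id=subject_id)


def write_edge_list(net: BinaryNetwork, path: str | Path) -> None:
    """Two-column TSV of edges (node_i < node_j)."""
    i, j = np.nonzero(np.triu(net.adjacency, 1))
    pd.DataFrame({"node_i": i, "node_j": j}).to_csv(path, sep="\t", index=False)
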