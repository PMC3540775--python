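"""Group-level inference: t-tests, node-wise permutation tests, FDR, correlations.

Global measures are compared with classical pooled-variance two-sample
t-tests.  Node-wise measures are compared with label-permutation tests (the
same permutation applied to every node, two-sided, add-one p estimator)
followed by Benjamini-Hochberg step-up FDR within each metric family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "two_sample_t",
    "pooled_t_statistic",
    "permutation_test_nodewise",
    "fdr_bh",
    "pearson_correlation_test",
    "compare_global_metrics",
    "compare_node_metrics",
    "GLOBAL_METRIC_COLUMNS",
]

#: Global measures compared between groups, in report order: the three
#: correlation-matrix grand means followed by the six topology measures.
GLOBAL_METRIC_COLUMNS = (
    "grand_mean_raw",
    "grand_mean_nonnegative",
    "grand_mean_thresholded",
    "L",
    "C",
    "gamma",
    "lambda",
    "sigma",
    "Q",
)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (df = n_a + n_b - 2), two-sided."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in t-test input")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if ((a.size - 1) * va + (b.size - 1) * vb) == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def pooled_t_statistic(x: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorized pooled two-sample t per column of ``x``.

    ``x`` is subjects x variables; ``mask_a`` is a boolean matrix
    (n_splits x subjects) selecting group A per split.  Columns with zero
    pooled variance get t = 0 (the no-evidence convention, so constant
    variables yield p = 1 under permutation).
    """
    x = np.asarray(x, float)
    mask_a = np.atleast_2d(np.asarray(mask_a, bool))
    n = x.shape[0]
    na = mask_a.sum(axis=1, keepdims=True).astype(float)
    nb = n - na
    m = mask_a.astype(float)
    sum_a = m @ x
    sumsq_a = m @ (x * x)
    tot = x.sum(axis=0, keepdims=True)
    totsq = (x * x).sum(axis=0, keepdims=True)
    sum_b = tot - sum_a
    sumsq_b = totsq - sumsq_a
    mean_a = sum_a / na
    mean_b = sum_b / nb
    ss_a = sumsq_a - na * mean_a**2
    ss_b = sumsq_b - nb * mean_b**2
    pooled = (ss_a + ss_b) / (na + nb - 2)
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / np.where(se > 0, se, 1.0), 0.0)
    return t


def permutation_test_nodewise(
    node_values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node two-sided permutation p-values for a two-group comparison.

    ``node_values`` is subjects x nodes; ``labels`` a boolean or two-level
    vector (True / first level = group A).  The statistic is the pooled
    two-sample t; the null permutes subject labels, identically across
    nodes; p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1).

    Returns (t_observed, p) arrays of length n_nodes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(node_values, float)
    if x.ndim != 2:
        raise ValueError("node_values must be subjects x nodes")
    labels = np.asarray(labels)
    if labels.dtype != bool:
        levels = pd.unique(labels)
        if levels.size != 2:
            raise ValueError(f"labels must have exactly 2 levels, got {levels.size}")
        labels = labels == levels[0]
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    if not np.isfinite(x).all():
        raise ValueError("node_values must be finite (impute or drop first)")

    t_obs = pooled_t_statistic(x, labels[None, :])[0]
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    perms = np.empty((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perms[i] = labels[rng.permutation(n)]
    t_perm = pooled_t_statistic(x, perms)
    exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return t_obs, p


def fdr_bh(
    p: np.ndarray, q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and significance flags."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q <= q_level


def pearson_correlation_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with its two-sided t-test on n - 2 degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def compare_global_metrics(
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    metric_columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-measure two-group comparison plus within-group C-Q correlations.

    ``metrics`` needs a ``group`` column (two levels) and one column per
    measure; defaults to :data:`GLOBAL_METRIC_COLUMNS` (intersected with
    what is present).  Returns one row per measure (scope
    ``global_metric``) and one per group for the clustering-modularity
    correlation (scope ``correlation``).
    """
    labels = sorted(metrics["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"expected 2 groups, got {labels}")
    g1, g2 = labels
    cols = [
        c
        for c in (metric_columns or GLOBAL_METRIC_COLUMNS)
        if c in metrics.columns
    ]
    a_all = metrics[metrics["group"] == g1]
    b_all = metrics[metrics["group"] == g2]
    rows = []
    for col in cols:
        a = a_all[col].to_numpy(float)
        b = b_all[col].to_numpy(float)
        t, p = two_sample_t(a, b)
        rows.append(
            {
                "scope": "global_metric",
                "identifier": col,
                f"mean_{g1}": a.mean(),
                f"sd_{g1}": a.std(ddof=1),
                f"mean_{g2}": b.mean(),
                f"sd_{g2}": b.std(ddof=1),
                "t": t,
                "p_t": p,
                "significant": p < alpha,
                "direction": f"{g1}_higher" if a.mean() > b.mean() else f"{g2}_higher",
            }
        )
    if {"C", "Q"} <= set(metrics.columns):
        for g, sub in ((g1, a_all), (g2, b_all)):
            if len(sub) < 3:  # correlation test needs n - 2 >= 1
                continue
            r, p = pearson_correlation_test(
                sub["C"].to_numpy(float), sub["Q"].to_numpy(float)
            )
            rows.append(
                {
                    "scope": "correlation",
                    "identifier": f"C_vs_Q[{g}]",
                    "r": r,
                    "p_t": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def compare_node_metrics(
    node_metrics: dict[str, np.ndarray],
    labels: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    fdr_level: float = 0.05,
    group_names: tuple[str, str] | None = None,
    significance_rule: str = "fdr",
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Node-wise permutation tests with BH-FDR within each metric family.

    ``node_metrics`` maps metric name -> subjects x nodes matrix; ``labels``
    is the per-subject group vector (aligned with the matrix rows).  Each
    metric gets its own permutation test (seeded independently but
    deterministically) and its own BH correction across nodes.

    ``significance_rule`` selects how the ``significant`` flag is set:
    ``"fdr"`` (default) uses the BH q-value at ``fdr_level``;
    ``"p_threshold"`` flags uncorrected permutation p-values below
    ``p_threshold`` instead (q-values are still reported).
    """
    if significance_rule not in ("fdr", "p_threshold"):
        raise ValueError(f"unknown significance_rule {significance_rule!r}")
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if levels.size != 2:
        raise ValueError(f"labels must have exactly 2 levels, got {levels.size}")
    if group_names is None:
        group_names = tuple(sorted(str(level) for level in levels))
    g1, g2 = group_names
    mask = labels == [level for level in levels if str(level) == g1][0]

    frames = []
    for idx, (name, values) in enumerate(sorted(node_metrics.items())):
        x = np.asarray(values, float).copy()
        bad = ~np.isfinite(x)
        if bad.any():
            # undefined node values (e.g. ED of an isolated node): impute the
            # node's finite mean so the permutation statistic stays defined
            col_mean = np.nanmean(np.where(bad, np.nan, x), axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            x[bad] = np.broadcast_to(col_mean, x.shape)[bad]
            warnings.warn(
                f"{int(bad.sum())} undefined {name} values imputed with node means",
                UserWarning,
                stacklevel=2,
            )
        metric_seed = int(
            np.random.SeedSequence([seed, idx]).generate_state(1)[0] & 0x7FFFFFFF
        )
        t_obs, p = permutation_test_nodewise(x, mask, n_perm=n_perm, seed=metric_seed)
        q, sig = fdr_bh(p, q_level=fdr_level)
        if significance_rule == "p_threshold":
            sig = p < p_threshold
        mean_a = x[mask].mean(axis=0)
        mean_b = x[~mask].mean(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "scope": "node_metric",
                    "metric": name,
                    "node_id": np.arange(x.shape[1]),
                    f"mean_{g1}": mean_a,
                    f"sd_{g1}": x[mask].std(axis=0, ddof=1),
                    f"mean_{g2}": mean_b,
                    f"sd_{g2}": x[~mask].std(axis=0, ddof=1),
                    "t": t_obs,
                    "p_perm": p,
                    "q": q,
                    "significant": sig,
                    "direction": np.where(
                        mean_a > mean_b, f"{g1}_higher", f"{g2}_higher"
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
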