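"""Synthetic multi-subject cohort generator for resting-state connectivity analysis.

The generator stands in for parcellated, demeaned regional BOLD time series.
Each region's signal is a linear mixture of latent unit-variance sources

    x_i(t) = g * h_i * s(t)  +  w * u_{m(i)}(t)  +  b * rho_i * v(t)  +  sd_eps * eps_i(t)

where ``s`` is a brain-wide global signal, ``u_c`` is a community (module)
signal shared by all regions of module ``m(i)``, ``v`` is a long-range signal
shared only by the flagged subset of spatially distant regions
(``rho_i`` in {0, 1}), and ``eps_i`` is region-private noise.  All sources are
AR(1)-smoothed and re-standardized to unit stationary variance, so the
population correlation between two regions has the closed form implemented in
:func:`expected_correlation`.

Group structure: the global coupling ``g`` and the long-range coupling ``b``
take group-specific values, so "case" cohorts exhibit a higher mean
cross-correlation and longer Euclidean reach at flagged nodes than "control"
cohorts.  The per-node loadings ``h_i`` (lognormal, mean one) model regional
heterogeneity of global-signal expression; without them, exact global-signal
subtraction downstream would cancel ``s`` identically and no group contrast
in the post-removal correlation matrices could exist.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneratorConfig",
    "SubjectRecord",
    "SUBCORTICAL_NAMES",
    "make_node_table",
    "simulate_subject",
    "simulate_cohort",
    "expected_correlation",
    "empirical_correlation",
]

GROUPS = ("control", "case")

#: The seven subcortical structures extracted per hemisphere.
SUBCORTICAL_NAMES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "amygdala",
    "accumbens",
    "hippocampus",
)

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Couplings are standard-deviation scales of the latent sources; the
    defaults are calibrated so that a default cohort reproduces the
    qualitative structure the analysis pipeline expects: near-zero
    post-global-signal-removal grand means with a positive case offset,
    modular binary networks at 20 % density with small-world organization,
    and longer connection reach at flagged nodes in cases.
    """

    n_nodes: int = 110
    n_volumes: int = 128
    n_modules: int = 8
    n_controls: int = 16
    n_cases: int = 14
    global_coupling_control: float = 1.45
    global_coupling_case: float = 1.95
    module_coupling: float = 1.0
    longrange_coupling_control: float = 0.4
    longrange_coupling_case: float = 1.3
    longrange_node_fraction: float = 0.1
    noise_sd: float = 1.0
    temporal_smoothing: float = 0.3
    global_loading_sd: float = 0.7
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.n_nodes % 2 != 0:
            raise ValueError(f"n_nodes must be even and >= 2, got {self.n_nodes}")
        if not 1 <= self.n_modules <= self.n_nodes // 2:
            raise ValueError(
                f"n_modules must be in [1, n_nodes/2], got {self.n_modules}"
            )
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.n_controls < 0 or self.n_cases < 0:
            raise ValueError("group sizes must be nonnegative")
        for name in (
            "global_coupling_control",
            "global_coupling_case",
            "module_coupling",
            "longrange_coupling_control",
            "longrange_coupling_case",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")
        if not math.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if not 0.0 <= self.longrange_node_fraction <= 1.0:
            raise ValueError("longrange_node_fraction must lie in [0, 1]")
        if not 0.0 <= self.temporal_smoothing < 1.0:
            raise ValueError("temporal_smoothing must lie in [0, 1)")
        if self.global_loading_sd < 0:
            raise ValueError("global_loading_sd must be nonnegative")

    def coupling_for(self, group: str) -> tuple[float, float]:
        """(global, long-range) coupling for ``group``."""
        if group == "control":
            return self.global_coupling_control, self.longrange_coupling_control
        if group == "case":
            return self.global_coupling_case, self.longrange_coupling_case
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a YAML or JSON file mirroring the field names."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SubjectRecord:
    """One subject's region x time signal matrix with its group label."""

    subject_id: str
    group: str
    series: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be a 2-D region x time matrix")
        if not np.all(np.isfinite(self.series)):
            raise ValueError(f"subject {self.subject_id}: non-finite series values")


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float) -> np.ndarray:
    """Unit-variance stationary AR(1) series along the last axis.

    Innovations are standard normal; the recursion is initialized from the
    stationary distribution and the output rescaled by sqrt(1 - phi^2) so the
    marginal variance is exactly one for every sample.
    """
    from scipy.signal import lfilter

    e = rng.standard_normal(shape)
    if phi == 0.0:
        return e
    head = shape[:-1]
    y_prev = rng.standard_normal(head + (1,)) / math.sqrt(1.0 - phi * phi)
    y, _ = lfilter([1.0], [1.0, -phi], e, axis=-1, zi=phi * y_prev)
    return y * math.sqrt(1.0 - phi * phi)


def _module_centers(rng: np.random.Generator, n_modules: int) -> np.ndarray:
    """Distinct module centers inside a +-70 mm box, min 40 mm apart."""
    centers = np.empty((n_modules, 3))
    placed = 0
    for _ in range(10_000):
        cand = rng.uniform(-70.0, 70.0, size=3)
        if placed == 0 or np.min(
            np.linalg.norm(centers[:placed] - cand, axis=1)
        ) >= 40.0:
            centers[placed] = cand
            placed += 1
            if placed == n_modules:
                return centers
    # Dense packing fallback: accept whatever spacing is achievable.
    while placed < n_modules:  # pragma: no cover - needs > ~15 modules
        centers[placed] = rng.uniform(-70.0, 70.0, size=3)
        placed += 1
    return centers


def _pair_names(n_pairs: int) -> list[str]:
    """Region base names; the last 7 pairs are the subcortical structures."""
    n_sub = len(SUBCORTICAL_NAMES) if n_pairs > len(SUBCORTICAL_NAMES) else 0
    n_ctx = n_pairs - n_sub
    names = [f"cortex-{i + 1:02d}" for i in range(n_ctx)]
    names += list(SUBCORTICAL_NAMES[:n_sub])
    return names


def make_node_table(config: GeneratorConfig) -> pd.DataFrame:
    """Build the node table: names, hemispheres, modules, geometry, flags.

    Nodes come in mirrored left/right pairs (pair ``p`` -> node ids ``2p`` and
    ``2p + 1``), both members sharing a module.  Modules occupy contiguous
    pair blocks; each node's centroid is its module's center plus isotropic
    8 mm jitter, with the right-hemisphere member mirrored in x.  Long-range
    flags are assigned to nodes of the most spatially distant module pairs so
    that raising the long-range coupling lengthens retained connections.

    Columns: node_id, name, hemisphere, module_id, longrange_flag,
    x_mm, y_mm, z_mm, global_loading.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 0]))
    n = config.n_nodes
    n_pairs = n // 2
    centers = _module_centers(rng, config.n_modules)

    pair_module = (np.arange(n_pairs) * config.n_modules) // n_pairs
    base_names = _pair_names(n_pairs)

    rows = []
    for p in range(n_pairs):
        m = int(pair_module[p])
        jitter = rng.normal(0.0, 8.0, size=3)
        left = centers[m] + jitter
        right = np.array([-left[0], left[1], left[2]])
        rows.append((2 * p, f"L-{base_names[p]}", "L", m, left))
        rows.append((2 * p + 1, f"R-{base_names[p]}", "R", m, right))

    table = pd.DataFrame(
        {
            "node_id": [r[0] for r in rows],
            "name": [r[1] for r in rows],
            "hemisphere": [r[2] for r in rows],
            "module_id": [r[3] for r in rows],
            "x_mm": [r[4][0] for r in rows],
            "y_mm": [r[4][1] for r in rows],
            "z_mm": [r[4][2] for r in rows],
        }
    )

    # Long-range flags: walk module pairs from most to least distant and
    # interleave their member nodes until the requested count is reached.
    n_flag = int(round(config.longrange_node_fraction * n))
    flags = np.zeros(n, dtype=bool)
    if n_flag > 0 and config.n_modules >= 2:
        dist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        pairs = [
            (dist[a, b], a, b)
            for a in range(config.n_modules)
            for b in range(a + 1, config.n_modules)
        ]
        pairs.sort(reverse=True)
        chosen: list[int] = []
        seen_modules: set[int] = set()
        for _, a, b in pairs:
            nodes_a = table.index[table.module_id == a].tolist()
            nodes_b = table.index[table.module_id == b].tolist()
            interleaved: list[int] = []
            for i in range(max(len(nodes_a), len(nodes_b))):
                if i < len(nodes_a):
                    interleaved.append(nodes_a[i])
                if i < len(nodes_b):
                    interleaved.append(nodes_b[i])
            for node in interleaved:
                if node not in chosen:
                    chosen.append(node)
            seen_modules.update((a, b))
            if len(chosen) >= n_flag:
                break
        flags[chosen[:n_flag]] = True
    elif n_flag > 0:
        flags[:n_flag] = True
    table["longrange_flag"] = flags

    loading = np.exp(rng.normal(0.0, config.global_loading_sd, size=n))
    table["global_loading"] = loading / loading.mean()

    return table[
        [
            "node_id",
            "name",
            "hemisphere",
            "module_id",
            "longrange_flag",
            "x_mm",
            "y_mm",
            "z_mm",
            "global_loading",
        ]
    ]


def simulate_subject(
    config: GeneratorConfig,
    node_table: pd.DataFrame,
    group: str,
    seed: int,
    subject_id: str = "subject",
    n_volumes: int | None = None,
) -> SubjectRecord:
    """Simulate one subject's region x time series for ``group``.

    Deterministic given ``seed``.  ``n_volumes`` may override the config
    (used by the long-series empirical calibration oracle).
    """
    g, b = config.coupling_for(group)
    w = config.module_coupling
    phi = config.temporal_smoothing
    T = config.n_volumes if n_volumes is None else int(n_volumes)
    n = config.n_nodes
    if len(node_table) != n:
        raise ValueError(
            f"node table has {len(node_table)} rows, config expects {n}"
        )

    rng = np.random.default_rng(seed)
    s = _ar1(rng, (T,), phi)
    u = _ar1(rng, (config.n_modules, T), phi)
    v = _ar1(rng, (T,), phi)
    eps = _ar1(rng, (n, T), phi)

    h = node_table["global_loading"].to_numpy(float)
    rho = node_table["longrange_flag"].to_numpy(bool).astype(float)
    module = node_table["module_id"].to_numpy(int)

    series = (
        g * h[:, None] * s[None, :]
        + w * u[module]
        + b * rho[:, None] * v[None, :]
        + config.noise_sd * eps
    )
    return SubjectRecord(subject_id, group, series, seed=seed)


def _subject_seeds(config: GeneratorConfig) -> np.ndarray:
    n = config.n_controls + config.n_cases
    state = np.random.SeedSequence([config.random_seed, 1]).generate_state(max(n, 1))
    return (state[:n] & _SEED_MASK).astype(np.int64)


def simulate_cohort(
    config: GeneratorConfig, node_table: pd.DataFrame | None = None
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Simulate the full two-group cohort.

    Per-subject seeds are derived from ``config.random_seed``, so cohorts are
    exactly reproducible; controls come first, then cases.
    """
    if node_table is None:
        node_table = make_node_table(config)
    seeds = _subject_seeds(config)
    records = []
    k = 0
    for group, size in (("control", config.n_controls), ("case", config.n_cases)):
        for i in range(size):
            sid = f"{group}-{i + 1:02d}"
            records.append(
                simulate_subject(config, node_table, group, int(seeds[k]), sid)
            )
            k += 1
    return records, node_table


def expected_correlation(
    config: GeneratorConfig,
    node_table: pd.DataFrame,
    node_i: int,
    node_j: int,
    group: str,
) -> float:
    """Closed-form population correlation between two regions (pre-removal).

    With per-node global loadings h and long-range flags rho,

        r_ij = (g^2 h_i h_j + w^2 [m(i)=m(j)] + b^2 rho_i rho_j)
               / sqrt((g^2 h_i^2 + w^2 + b^2 rho_i + sd^2)
                      (g^2 h_j^2 + w^2 + b^2 rho_j + sd^2)).

    This is the expectation for the simulated series as generated; the
    analysis pipeline's global-signal removal alters correlations, for which
    :func:`empirical_correlation` with ``remove_global=True`` is the
    calibration oracle.
    """
    if node_i == node_j:
        raise ValueError("expected_correlation is undefined for i == j")
    g, b = config.coupling_for(group)
    w = config.module_coupling
    sd2 = config.noise_sd**2
    h = node_table["global_loading"].to_numpy(float)
    rho = node_table["longrange_flag"].to_numpy(bool).astype(float)
    module = node_table["module_id"].to_numpy(int)
    same = 1.0 if module[node_i] == module[node_j] else 0.0
    num = (
        g * g * h[node_i] * h[node_j]
        + w * w * same
        + b * b * rho[node_i] * rho[node_j]
    )
    var_i = g * g * h[node_i] ** 2 + w * w + b * b * rho[node_i] + sd2
    var_j = g * g * h[node_j] ** 2 + w * w + b * b * rho[node_j] + sd2
    if var_i == 0.0 or var_j == 0.0:
        return 0.0
    return float(num / math.sqrt(var_i * var_j))


def empirical_correlation(
    config: GeneratorConfig,
    node_table: pd.DataFrame,
    group: str,
    n_volumes: int = 100_000,
    seed: int = 12345,
    remove_global: bool = False,
) -> np.ndarray:
    """Monte-Carlo correlation matrix from one long simulated series.

    With ``remove_global=True`` the across-node mean time course is
    subtracted first, yielding the post-removal calibration oracle.
    """
    rec = simulate_subject(
        config, node_table, group, seed, subject_id="oracle", n_volumes=n_volumes
    )
    x = rec.series - rec.series.mean(axis=1, keepdims=True)
    if remove_global:
        x = x - x.mean(axis=0, keepdims=True)
    return np.corrcoef(x)


# ---------------------------------------------------------------------------
# On-disk cohort format
# ---------------------------------------------------------------------------

def write_cohort(
    records: list[SubjectRecord],
    node_table: pd.DataFrame,
    outdir: str | Path,
) -> Path:
    """Write a cohort: per-subject series TSVs, node table TSV, manifest JSON.

    Series files are tab-separated, one row per node, one column per volume,
    no header.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        fname = f"{rec.subject_id}.tsv"
        np.savetxt(outdir / fname, rec.series, delimiter="\t", fmt="%.10g")
        entries.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "path": fname,
                "seed": int(rec.seed),
            }
        )
    node_table.to_csv(outdir / "nodes.tsv", sep="\t", index=False)
    manifest = {"node_table": "nodes.tsv", "subjects": entries}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path
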