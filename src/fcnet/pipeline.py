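"""End-to-end orchestration: simulate/load -> connectivity -> metrics -> inference.

Every run is controlled by a single ``master_seed``; each stage draws its
randomness from a seed derived as
``SeedSequence([master_seed, stage_index]).generate_state(1)[0] & 0x7FFFFFFF``
(stage indices: 0 generator, 1 per-subject benchmark root, 2 modularity,
3 node-wise permutation tests), so stages can be re-run in isolation and two
runs with the same configuration produce identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    correlation_matrix,
    demean,
    grand_mean,
    remove_global_signal,
    retained_correlation_summary,
    threshold_by_density,
    write_edge_list,
    write_matrix_tsv,
    zero_negatives,
)
from .metrics import subject_metrics
from .simulate import GeneratorConfig, SubjectRecord, simulate_cohort, write_cohort
from .spatial import hub_frequency, neighbor_mean_distance, seed_profile, top_hubs
from .stats import compare_global_metrics, compare_node_metrics

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_cohort", "stage_seed"]

_STAGES = ("simulate", "connect", "metrics", "compare")
_SEED_MASK = 0x7FFFFFFF


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master_seed, stage_index]).generate_state(1)[0]
        & _SEED_MASK
    )


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort_manifest: str | None = None  # load instead of simulating
    density: float = 0.20
    hub_set_size: int = 15
    seed_node: int | str = "R-caudate"
    n_perm: int = 5000
    fdr_level: float = 0.05
    node_significance_rule: str = "fdr"  # or "p_threshold" (uncorrected p)
    node_p_threshold: float = 0.01
    benchmark_realizations: int = 100
    output_dir: str = "fcnet-run"
    master_seed: int = 0
    save_matrices: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.n_perm < 1 or self.hub_set_size < 1 or self.benchmark_realizations < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        gen = data.pop("generator", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(generator=GeneratorConfig(**gen), **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Machine-readable record of one run."""

    config: dict
    stage_counts: dict
    files: list[str]
    warnings: list[str]
    version: str
    elapsed: dict

    def to_json(self, path: str | Path, include_elapsed: bool = True) -> None:
        d = dataclasses.asdict(self)
        if not include_elapsed:
            d.pop("elapsed")
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def load_cohort(
    manifest_path: str | Path,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Load a cohort written by :func:`fcnet.simulate.write_cohort`.

    Validates shapes against the node table, requires unique subject ids and
    exactly two group labels; arbitrary labels are mapped to control/case by
    an optional ``label_map`` manifest entry
    (``{"control": <label>, "case": <label>}``).
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    subjects = manifest.get("subjects", [])
    if not subjects:
        raise ValueError(f"{manifest_path}: empty subject list")
    node_table = pd.read_csv(root / manifest["node_table"], sep="\t")
    n_nodes = len(node_table)

    label_map = manifest.get("label_map")
    raw_labels = {e["group"] for e in subjects}
    if len(raw_labels) > 2:
        raise ValueError(
            f"{manifest_path}: expected at most 2 group labels, got {sorted(raw_labels)}"
        )
    if label_map is not None:
        inverse = {v: k for k, v in label_map.items()}
        missing = raw_labels - set(inverse)
        if missing:
            raise ValueError(f"label_map does not cover labels {sorted(missing)}")
    else:
        unknown = raw_labels - {"control", "case"}
        if unknown:
            raise ValueError(
                f"unknown group label(s) {sorted(unknown)}; "
                "declare a label_map in the manifest"
            )
        inverse = {"control": "control", "case": "case"}

    records = []
    seen: set[str] = set()
    for entry in subjects:
        sid = entry["subject_id"]
        if sid in seen:
            raise ValueError(f"duplicate subject_id {sid!r}")
        seen.add(sid)
        path = root / entry["path"]
        try:
            series = np.loadtxt(path, delimiter="\t", ndmin=2)
        except Exception as exc:
            raise ValueError(f"malformed series file {path}: {exc}") from exc
        if series.shape[0] != n_nodes:
            raise ValueError(
                f"series file {path}: {series.shape[0]} rows, "
                f"node table has {n_nodes}"
            )
        records.append(
            SubjectRecord(sid, inverse[entry["group"]], series, seed=entry.get("seed", 0))
        )
    shapes = {r.series.shape for r in records}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent series shapes across subjects: {shapes}")
    return records, node_table


def _resolve_seed_node(seed_node: int | str, node_table: pd.DataFrame) -> int:
    if isinstance(seed_node, (int, np.integer)):
        if not 0 <= seed_node < len(node_table):
            raise ValueError(f"seed node id {seed_node} out of range")
        return int(seed_node)
    match = node_table.index[node_table["name"] == seed_node]
    if len(match) != 1:
        raise ValueError(f"seed node name {seed_node!r} not found in node table")
    return int(node_table.loc[match[0], "node_id"])


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = _STAGES) -> RunReport:
    """Execute the pipeline stage prefix given by ``stages``.

    Writes all artifacts under ``config.output_dir`` and returns the run
    report (also written as ``report.json`` plus a human-readable
    ``summary.txt``).
    """
    for s in stages:
        if s not in _STAGES:
            raise ValueError(f"unknown stage {s!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    counts: dict[str, int] = {}
    elapsed: dict[str, float] = {}
    caught: list[str] = []

    def _note(path: Path) -> Path:
        files.append(str(path.relative_to(outdir)))
        return path

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # --- stage: simulate or load -----------------------------------
        t0 = time.perf_counter()
        if config.cohort_manifest is not None:
            records, node_table = load_cohort(config.cohort_manifest)
        else:
            gen = dataclasses.replace(
                config.generator, random_seed=stage_seed(config.master_seed, 0)
            )
            records, node_table = simulate_cohort(gen)
            cohort_dir = outdir / "cohort"
            manifest = write_cohort(records, node_table, cohort_dir)
            _note(manifest)
        counts["subjects"] = len(records)
        counts["nodes"] = len(node_table)
        elapsed["simulate"] = time.perf_counter() - t0
        groups = {r.subject_id: r.group for r in records}

        result = RunReport(
            config=config.to_dict(),
            stage_counts=counts,
            files=files,
            warnings=caught,
            version=__version__,
            elapsed=elapsed,
        )

        if "connect" in stages:
            # --- stage: connectivity ------------------------------------
            t0 = time.perf_counter()
            conn_dir = outdir / "connectivity"
            conn_dir.mkdir(exist_ok=True)
            nets = []
            conn_rows = []
            for rec in records:
                x = remove_global_signal(demean(rec.series))
                cm = correlation_matrix(x, subject_id=rec.subject_id)
                gm_raw = grand_mean(cm)
                gm_nonneg = grand_mean(zero_negatives(cm))
                thr, gm_thr = retained_correlation_summary(cm, config.density)
                net = threshold_by_density(cm, config.density)
                nets.append(net)
                if config.save_matrices:
                    write_matrix_tsv(cm, _note(conn_dir / f"{rec.subject_id}_corr.tsv"))
                write_edge_list(net, _note(conn_dir / f"{rec.subject_id}_edges.tsv"))
                conn_rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "grand_mean_raw": gm_raw,
                        "grand_mean_nonnegative": gm_nonneg,
                        "grand_mean_thresholded": gm_thr,
                        "threshold_value": thr,
                        "n_edges": net.n_edges,
                        "edge_density": net.edge_density,
                    }
                )
            conn_df = pd.DataFrame(conn_rows)
            conn_df.to_csv(
                _note(outdir / "connectivity_summary.tsv"), sep="\t", index=False
            )
            counts["edges_per_subject"] = int(conn_df["n_edges"].iloc[0])
            elapsed["connect"] = time.perf_counter() - t0

        if "metrics" in stages and "connect" in stages:
            # --- stage: graph + spatial metrics -------------------------
            t0 = time.perf_counter()
            bench_root = stage_seed(config.master_seed, 1)
            subj_rows, node_rows = [], []
            degrees = {}
            cohort_metrics = []
            for idx, (rec, net) in enumerate(zip(records, nets)):
                subj_seed = int(
                    np.random.SeedSequence([bench_root, idx]).generate_state(1)[0]
                    & _SEED_MASK
                )
                sm = subject_metrics(
                    net,
                    n_realizations=config.benchmark_realizations,
                    seed=subj_seed,
                )
                ed = neighbor_mean_distance(net, node_table)
                degrees[rec.subject_id] = sm.degree
                cohort_metrics.append(sm)
                subj_rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "L": sm.L,
                        "C": sm.C,
                        "gamma": sm.gamma,
                        "lambda": sm.lambda_,
                        "sigma": sm.sigma,
                        "Q": sm.Q,
                    }
                )
                node_rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": rec.subject_id,
                            "group": rec.group,
                            "node_id": np.arange(net.n_nodes),
                            "k": sm.degree,
                            "C_i": sm.local_clustering,
                            "L_i": sm.local_path_length,
                            "sigma_i": sm.local_sigma,
                            "mean_neighbor_distance": ed["mean_neighbor_distance"],
                        }
                    )
                )
            subj_df = pd.DataFrame(subj_rows).merge(
                conn_df[
                    [
                        "subject_id",
                        "grand_mean_raw",
                        "grand_mean_nonnegative",
                        "grand_mean_thresholded",
                    ]
                ],
                on="subject_id",
            )
            node_df = pd.concat(node_rows, ignore_index=True)
            subj_df.to_csv(_note(outdir / "subject_metrics.tsv"), sep="\t", index=False)
            node_df.to_csv(_note(outdir / "node_metrics.tsv"), sep="\t", index=False)

            # hub frequency and Table-3-style hub ranking
            hub_freq = hub_frequency(degrees, groups, config.hub_set_size)
            hub_freq = hub_freq.merge(
                node_table[["node_id", "name"]], on="node_id"
            )
            hub_freq.to_csv(_note(outdir / "hub_frequency.tsv"), sep="\t", index=False)
            hub_rows = []
            for g in sorted(set(groups.values())):
                ids = [sid for sid, gg in groups.items() if gg == g]
                mean_k = np.mean([degrees[sid] for sid in ids], axis=0)
                for rank, node in enumerate(top_hubs(mean_k, config.hub_set_size), 1):
                    hub_rows.append(
                        {
                            "group": g,
                            "rank": rank,
                            "node_id": int(node),
                            "name": node_table.loc[node, "name"],
                            "mean_k": mean_k[node],
                        }
                    )
            pd.DataFrame(hub_rows).to_csv(
                _note(outdir / "hub_table.tsv"), sep="\t", index=False
            )

            # seed-region profile
            seed_id = _resolve_seed_node(config.seed_node, node_table)
            profile = seed_profile(nets, groups, seed_id)
            prof = profile.table.merge(node_table[["node_id", "name"]], on="node_id")
            prof.to_csv(_note(outdir / "seed_profile.tsv"), sep="\t", index=False)
            counts["seed_node_id"] = seed_id
            counts["seed_specific_connections"] = sum(
                len(v) for v in profile.group_specific_nodes.values()
            )
            elapsed["metrics"] = time.perf_counter() - t0

        if "compare" in stages and "metrics" in stages:
            # --- stage: group comparison --------------------------------
            t0 = time.perf_counter()
            global_cmp = compare_global_metrics(subj_df)
            global_cmp.to_csv(
                _note(outdir / "global_comparison.tsv"), sep="\t", index=False
            )

            labels = np.array([groups[r.subject_id] for r in records])
            pivot = {
                name: node_df.pivot(
                    index="subject_id", columns="node_id", values=col
                )
                .loc[[r.subject_id for r in records]]
                .to_numpy(float)
                for name, col in (
                    ("degree", "k"),
                    ("local_clustering", "C_i"),
                    ("local_path_length", "L_i"),
                    ("mean_neighbor_distance", "mean_neighbor_distance"),
                )
            }
            node_cmp = compare_node_metrics(
                pivot,
                labels,
                n_perm=config.n_perm,
                seed=stage_seed(config.master_seed, 3),
                fdr_level=config.fdr_level,
                significance_rule=config.node_significance_rule,
                p_threshold=config.node_p_threshold,
            )
            node_cmp = node_cmp.merge(node_table[["node_id", "name"]], on="node_id")
            node_cmp.to_csv(
                _note(outdir / "node_comparison.tsv"), sep="\t", index=False
            )
            counts["node_tests_significant"] = int(node_cmp["significant"].sum())
            elapsed["compare"] = time.perf_counter() - t0

        caught.extend(f"{w.category.__name__}: {w.message}" for w in wrec)

    result.to_json(outdir / "report.json")
    _summary(result, outdir / "summary.txt")
    return result


def _summary(report: RunReport, path: Path) -> None:
    lines = [
        f"fcnet {report.version} run summary",
        f"subjects: {report.stage_counts.get('subjects')}"
        f"  nodes: {report.stage_counts.get('nodes')}",
    ]
    for key in ("edges_per_subject", "seed_node_id", "seed_specific_connections",
                "node_tests_significant"):
        if key in report.stage_counts:
            lines.append(f"{key}: {report.stage_counts[key]}")
    for stage, secs in report.elapsed.items():
        lines.append(f"elapsed[{stage}]: {secs:.2f} s")
    if report.warnings:
        lines.append(f"warnings: {len(report.warnings)}")
    Path(path).write_text("\n".join(lines) + "\n")
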