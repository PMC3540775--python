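# fcnet — resting-state functional-connectivity network analysis

`fcnet` is a reusable pipeline for graph-theoretic analysis of resting-state
functional connectivity (FC) in two-group study designs (e.g. patients vs.
controls). It starts from parcellated region × time signal matrices — the
kind produced by averaging a BOLD signal within atlas regions — and carries
them through correlation-network construction, topological and spatial
characterization, and group-level inference. Because region-level fMRI data
are rarely shareable, the package also ships a calibrated synthetic cohort
generator, so every analysis step is exercised end to end on data with known
ground truth.

## What it computes

**Connectivity.** Per subject: row demeaning, global-signal removal
(subtraction of the across-node mean time course), the Pearson correlation
matrix *R* over all region pairs (self-correlations excluded), a
non-negative variant (negative entries zeroed), and a binary network
obtained by *proportional thresholding*: the top 20 % of positive
correlations become edges, so every subject has the same edge count — a
prerequisite for comparing topology across subjects.

**Topology.** For each binary network: characteristic path length *L*
(mean shortest-path length over reachable pairs), clustering coefficient
*C*, modularity *Q* (Newman definition, Louvain-optimized with
deterministic restarts), and the benchmark-normalized ratios

γ = C / C_r,  λ = L / L_r,  σ = γ / λ = C·L_r / (C_r·L),

where C_r and L_r are means over uniform random graphs with identical node
and edge counts. σ ≫ 1 indicates small-world organization. Node-wise:
degree k_i, local clustering C_i, local path length L_i.

**Spatial structure.** The Euclidean distance (mm) between centroids of
connected regions approximates connection reach; each node's mean neighbor
distance summarizes how far its functional partners lie. Hubs are the 15
highest-degree nodes per subject; hub frequency per group exposes shifts in
the network core. A configurable seed region (default: the right caudate)
gets a cross-subject connection profile with group-specific partners and a
pooled two-proportion z-test (|z| > 2) on shared connections.

**Inference.** Global measures: pooled-variance two-sample t-tests, plus
within-group Pearson tests (C vs. Q). Node-wise measures: label-permutation
tests (5,000 permutations by default, the same permutation applied to every
node, two-sided add-one p-values) with Benjamini–Hochberg FDR at 5 % within
each metric family.

**Synthetic cohorts.** Region signals are latent-factor mixtures
`x_i(t) = g·h_i·s(t) + w·u_m(i)(t) + b·ρ_i·v(t) + σ_ε·ε_i(t)` with a global
signal s, module signals u, a long-range signal v shared by flagged nodes
in spatially distant modules, AR(1) temporal smoothing, and per-node global
loadings h_i. Group-specific couplings (g, b) produce the two calibrated
contrasts: higher mean cross-correlation and longer connection reach at
flagged nodes in cases. A closed-form correlation oracle
(`expected_correlation`) makes the generator testable against Monte-Carlo.

## Worked example

Run the default study design — 16 controls vs. 14 cases, 110 regions,
128 volumes — end to end:

```bash
fcnet run --output-dir demo-run --master-seed 42
fcnet report --output-dir demo-run
```

which prints

```
fcnet 0.1.0 run summary
subjects: 30  nodes: 110
edges_per_subject: 1199
seed_node_id: 99
seed_specific_connections: 13
node_tests_significant: 266
```

Every subject's network keeps exactly 1,199 of the 5,995 region pairs
(20 % edge density). Node 99 is the right-caudate analog; 13 of its
connections occur in only one group. Highlights from the output tables of
this run (`connectivity_summary.tsv`, `global_comparison.tsv`,
`node_comparison.tsv`):

| quantity (group mean)        | controls | cases  |
|------------------------------|----------|--------|
| raw grand mean correlation   | −0.0079  | −0.0064 |
| correlation at the 20 % cutoff | 0.21   | 0.29   |
| mean retained correlation    | 0.385    | 0.459  |
| path length L                | 2.11     | 2.27   |
| clustering C                 | 0.64     | 0.68   |
| small-worldness σ            | 2.75     | 2.72   |
| modularity Q                 | 0.42     | 0.45   |

The raw grand mean sits near zero (global-signal removal centers the
correlation distribution) but is significantly higher in cases
(t = 11.2, p < 10⁻¹¹) — the generator's elevated case global coupling
surviving global-signal removal through regional loading heterogeneity.
σ ≈ 2.7 in both groups indicates strong small-world organization. Of the
node-wise mean-neighbor-distance tests, 36 nodes pass 5 % FDR, 32 of them
with longer reach in cases — the calibrated long-range effect. All outputs
are tab-separated tables; rerunning with the same `--master-seed`
reproduces every file bit for bit.

Library use mirrors the CLI:

```python
from fcnet import (GeneratorConfig, simulate_cohort, demean,
                   remove_global_signal, correlation_matrix,
                   threshold_by_density, subject_metrics)

records, nodes = simulate_cohort(GeneratorConfig(random_seed=7))
x = remove_global_signal(demean(records[0].series))
net = threshold_by_density(correlation_matrix(x), density=0.20)
print(subject_metrics(net, seed=1).sigma)
```

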