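# Methods

This note documents the models, conventions and numerical choices behind
`fcnet`, in the order the pipeline applies them.

## Synthetic cohort model

Each subject's region × time matrix is a linear mixture of independent
latent sources, all AR(1)-smoothed and re-standardized to unit stationary
variance:

    x_i(t) = g · h_i · s(t) + w · u_{m(i)}(t) + b · ρ_i · v(t) + σ_ε · ε_i(t)

- `s` — brain-wide global signal; coupling `g` is group-specific
  (`global_coupling_control` / `global_coupling_case`).
- `u_c` — one signal per module (community); every region of module
  `m(i)` loads on it with weight `w` (`module_coupling`). Modules are
  contiguous blocks of mirrored left/right region pairs.
- `v` — long-range signal shared only by the flagged subset of regions
  (`ρ_i ∈ {0,1}`), with group-specific coupling `b`. Flagged regions are
  drawn from the most spatially distant module pairs so that raising `b`
  lengthens retained connections by construction.
- `ε_i` — region-private noise with standard deviation `σ_ε`.
- `h_i` — per-region global-signal loading, lognormal with unit mean and
  log-sd `global_loading_sd`, drawn once per node table.

The population correlation of two regions before any signal removal is

    r_ij = (g²h_ih_j + w²·[m(i)=m(j)] + b²ρ_iρ_j)
           / sqrt((g²h_i² + w² + b²ρ_i + σ_ε²)(g²h_j² + w² + b²ρ_j + σ_ε²))

implemented as `expected_correlation` and verified against long-run
simulation (T = 10⁵) to within ±0.01. With `global_loading_sd = 0` the
loadings drop out and the formula reduces to the homogeneous special case.

**Why heterogeneous loadings.** Global-signal removal here is *exact*
subtraction of the across-node mean time course. A shared signal entering
every region with identical weight is cancelled identically by that
subtraction, so no group contrast carried purely by `g` could survive the
pipeline. Real regional BOLD expresses the global signal with regionally
varying strength, which is why empirical studies still observe grand-mean
differences after removal. The lognormal loadings model exactly that:
after subtraction a residual global component with loadings
`g(h_i − h̄)` remains, and the grand mean of the post-removal correlation
matrix increases monotonically with `g` (verified empirically over a
coupling grid). `empirical_correlation(..., remove_global=True)` is the
post-removal calibration oracle.

**Defaults** (units are signal standard deviations unless noted):

| parameter | default | role |
|---|---|---|
| n_nodes / n_volumes | 110 / 128 | parcellation size and series length of the emulated study design |
| n_controls / n_cases | 16 / 14 | group sizes of the emulated design |
| n_modules | 8 | bilateral communities; gives ~14-node modules |
| g control → case | 1.45 → 1.95 | global coupling; drives the grand-mean contrast |
| w | 1.0 | module coupling; sets within-module correlation ≈ 0.3–0.5 |
| b control → case | 0.4 → 1.3 | long-range coupling at flagged nodes; drives the reach contrast |
| longrange_node_fraction | 0.1 | 11 flagged nodes in the two most distant modules |
| σ_ε | 1.0 | private noise |
| temporal_smoothing | 0.3 | AR(1) coefficient emulating slow fluctuations; 0 (white noise) is valid since only fixed-T Pearson correlation consumes the series |
| global_loading_sd | 0.7 | regional heterogeneity of global-signal expression |

The effect sizes were calibrated once, against the reference values of the
emulated study design (near-zero grand means with a positive case offset of
a few 10⁻³, a correlation cutoff near r ≈ 0.28 at 20 % density, and
small-world topology with L ≈ 2.2, C ≈ 0.6, σ ≈ 2–3, Q ≈ 0.4), using the
post-removal oracle. Geometry: module centers are sampled uniformly in a
±70 mm box with ≥40 mm separation; node centroids add isotropic 8 mm
jitter and are mirrored in x across hemispheres. Names follow the
emulated parcellation: 48 cortical plus 7 subcortical regions per
hemisphere (thalamus, caudate, putamen, pallidum, amygdala, accumbens,
hippocampus) when the table is large enough to hold them.

**What the generator does not emulate:** hemodynamic response shapes,
scanner and physiological noise, motion artifacts, band-limited (0.01–0.1
Hz) spectra, spatial smoothness across neighboring regions, volumetric
data of any kind, or realistic atlas geometry. Passing tests therefore
demonstrate correctness of the *analysis machinery* and directional
recoverability of the two built-in effects; they do not certify behavior
on real BOLD data. Note also that at the calibrated defaults the coupling
contrast mildly perturbs aggregate topology (L, C, Q differ between
synthetic groups), so the synthetic cohort is not a model of studies in
which topology is preserved between groups.

## Connectivity conventions

- Order of operations: demean → global-signal removal → Pearson
  correlation. Both preprocessing steps are idempotent.
- The matrix diagonal is stored as 1 but excluded from every summary; the
  grand mean averages the n(n−1)/2 upper-triangle entries.
- Proportional thresholding keeps the top `floor(density · n(n−1)/2)`
  correlations as edges. Only strictly positive correlations are eligible;
  if fewer are available than requested the network keeps all positive
  ones and a `ThresholdWarning` records the shortfall. Ties at the cutoff
  are broken by ascending (i, j) node index — ties have measure zero on
  continuous data but occur in toy examples, and a deterministic rule
  keeps runs reproducible. Flooring guarantees realized density ≤
  requested density. At the default 20 % on 110 nodes this yields exactly
  1,199 edges per subject.
- The thresholded grand mean is computed over retained entries only (the
  alternative — averaging with zeros included — would simply rescale it by
  the density).

## Graph measures

- `L` averages shortest-path lengths over *reachable ordered pairs*;
  unreachable pairs are excluded with a warning stating how many. At 20 %
  density networks are essentially always connected, so the convention
  only matters for degenerate inputs. `L_i` is the mean distance from
  node i to the nodes reachable from it (NaN for isolated nodes).
- `C_i` = 0 when degree < 2 (no neighbor pairs to close); `C` is the
  unweighted mean over all nodes.
- The random benchmark is the uniform G(n, m) model — same node and edge
  count, not degree-preserving — averaged over 100 realizations by
  default. For G(110, 1199), C_r ≈ edge density ≈ 0.2.
- Modularity uses the Newman quality function; optimization is Louvain
  with 8 deterministic restarts (seeds derived from the stage seed),
  keeping the best-Q partition. Restarts remove most single-run
  variability of the heuristic on small graphs; on exhaustive-search
  fixtures (≤ 6 nodes) the returned Q is never above, and at least 90 %
  of, the true optimum. `modularity_q` evaluates a *given* partition and
  is exposed separately so the optimizer can be tested against oracles.
- The node-wise small-world index `sigma_i = C_i·L_r/(C_r·L_i)` applies
  the subject's global benchmark to local measures; it is an
  interpretation (no standard definition exists) and is reported but not
  used by any decision rule.

## Spatial and seed statistics

- Mean neighbor distance is undefined (NaN, `defined_flag = False`) for
  isolated nodes; downstream group tests impute such values with the
  node's finite cross-subject mean and warn.
- Hubs: top 15 nodes by degree, ties broken by node id. Hub frequency is
  the fraction of a group's subjects in which a node makes the hub set;
  columns sum to the hub-set size by construction.
- Seed profile: a seed connection is attributed to a group when its
  within-group frequency reaches the attribution threshold (default: one
  subject, the weakest literal reading of "present in the group"; stricter
  consensus thresholds are a parameter). Group-specific means attributed
  in one group and present in zero subjects of the other. The pooled
  two-proportion z-test is applied only to connections present in both
  groups; a pooled proportion of 0 or 1 leaves z undefined (flagged, not
  significant).

## Inference

- Global measures use the classical pooled-variance two-sample t-test
  (df = n₁ + n₂ − 2). The comparison battery covers the three grand means
  (raw, non-negative, thresholded) and L, C, γ, λ, σ, Q, plus the
  within-group Pearson test of C against Q (skipped for groups with
  fewer than three subjects).
- Node-wise tests permute subject labels — the same permutation for every
  node, preserving the cross-node dependence structure — and use the
  pooled t as statistic with the two-sided add-one estimator
  p = (1 + #{|t_perm| ≥ |t_obs|}) / (n_perm + 1). Nodes with zero pooled
  variance get t = 0, hence p = 1. BH step-up FDR is applied within each
  metric family (110 tests each) at 5 %. An alternative uncorrected
  p < 0.01 flagging rule is available via
  `significance_rule="p_threshold"`.
- Because permutation p-values are discrete (minimum 1/(n_perm+1)), BH
  over 110 tests cannot reject a lone extreme p at 5,000 or fewer
  permutations; rejections require several jointly small p-values. Under
  a complete null this makes the realized false-discovery rate
  conservative (well below 5 %), which the null-simulation study in
  `scripts/acceptance.py` measures directly.

## Determinism and seeds

All randomness flows from one `master_seed`. Stage seeds are
`SeedSequence([master_seed, stage_index])` (0 generator, 1 benchmark root,
2 modularity restarts, 3 permutation tests), truncated below 2³¹;
per-subject and per-metric seeds extend the same scheme, so any stage can
be re-run in isolation. Two runs with identical configuration produce
byte-identical output files; the run report additionally records per-stage
wall-clock times and the echoed output directory, which are the only
fields excluded from reproducibility comparisons.

## Problem sizes used by the test and validation suites

Unit and property tests run on 10–40-node cohorts; the calibration oracle
uses 12 nodes at T = 10⁵; directional-recovery power checks run 50
replicates of the full 110-node, 30-subject design with 999 permutations;
the null error-control study uses 100 replicates with 1,000 permutations
(40 replicates at 250 permutations inside the test suite). These sizes
keep the whole suite to roughly half a minute while leaving every
statistical check well-powered.

## Known limitations

- The generator's two effects are injected through shared latent signals;
  real group differences in FC arise from far richer mechanisms, and the
  calibration should not be read as a biophysical model.
- The benchmark model is G(n, m); degree-preserving rewiring would give
  slightly different γ, λ for heavy-tailed degree distributions.
- Permutation tests assume exchangeability of subjects under the null; no
  covariate adjustment is provided.
- Weighted-graph metrics, efficiency/betweenness measures, partial
  correlations and frequency-resolved connectivity are out of scope.
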