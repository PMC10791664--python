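# Methods

This note documents the models, conventions, and design choices behind
`fconn`, in the spirit of a package methods appendix: what each stage
computes, which knobs matter, what the synthetic data do and do not
emulate, and where genuinely open choices were resolved.

## Connectome construction

Edge weights are *pairwise* partial correlations: each node's time
course is residualized on the confound series (plus an intercept) and
the Pearson correlation of the residuals is taken. Other nodes are not
partialed out — inverting the full precision matrix over hundreds of
nodes would demand more time points than nodes, which resting-state
scans rarely provide, and the pairwise form matches how confound
control ("controlling average time courses extracted from white matter
and ventricles") is conventionally done.

The fixed stage order is raw partial correlation → negative clipping →
Fisher z. Clipping before the z-transform follows the order the
procedure is usually described in; because artanh(0) = 0 and artanh is
increasing, the two orders coincide on nonnegative entries, and the
alternative order is nevertheless exposed
(`build_connectivity(clip_before_z=False)`) since published
descriptions leave it ambiguous. Correlations of exactly 1 (duplicate
series) are capped at 1 − 10⁻⁷ before artanh so edge weights stay
finite for the spanning-tree filter.

Session concatenation z-standardizes every node and confound series
per session before joining. This removes inter-session offset and
scale, which would otherwise masquerade as shared signal; raw
concatenation is available (`standardize=False`) because the original
convention is unstated.

## OMST topological filtering

Minimum spanning trees are extracted with Kruskal's algorithm on
distances d = 1/w, so each tree retains the strongest available
backbone; after each round the tree's edges are removed from the
candidate pool, making the trees pairwise edge-disjoint. After round m
the aggregated union U_m is scored by global cost efficiency

    GCE(m) = E(U_m) / E(G) − cost(m),

with E global efficiency, G the unfiltered graph, and cost(m) the
selected fraction of total edge weight. Three conventions are fixed
here and config-exposed:

- **Efficiency normalization.** E(U_m) is divided by E(G) so that the
  efficiency term and the cost term share the [0, 1] scale and their
  difference is meaningful; the full graph then scores exactly 0.
- **Stopping and selection.** Rounds continue until no spanning tree
  exists or `max_trees` (default 50) is reached; the returned union is
  the *global* argmax of the GCE curve (first maximum on exact ties),
  which is deterministic, rather than the first local maximum.
- **Tie-breaking.** Kruskal candidates are sorted by (distance, smaller
  node index, larger node index), making the output invariant across
  runs even under weight ties.

The output is connected by construction (it contains the first tree);
orthogonality is asserted on every run.

## Graph metrics

All path-based metrics use d_ij = 1/w_ij distances and exact Dijkstra
(scipy's csgraph); a Floyd–Warshall implementation exists only as a
test oracle. Clustering uses the geometric-mean (Onnela-style) triangle
intensity t_i = ½ Σ (ŵ_ij ŵ_ih ŵ_jh)^{1/3} on weights normalized by the
*global* maximum — the simplest reading of "normalized to be between 0
and 1" — with C_i := 0 for nodes of degree < 2. This keeps every C_i in
[0, 1] and makes clustering invariant to uniform rescaling of all
weights, a fact the synthetic effect design exploits (below).

Small-world propensity compares the observed clustering and
characteristic path length with matched nulls: a ring lattice with the
same node and edge count whose edges are filled in order of increasing
ring distance with the observed weights sorted descending, and random
nulls with edges placed uniformly and weights randomly assigned,
rejecting disconnected draws (cap 100 attempts; the error suggests a
denser graph). Δ_C and Δ_L are clamped to [0, 1]; degenerate
denominators map to 0 (numerator ≤ 0) or 1. Random-null statistics
average over `n_null` (default 10) seeded realizations. If the sparse
lattice null is disconnected its path length falls back to the observed
value, which the clamp absorbs. The number of null realizations and the
handling of disconnected nulls are documented choices, not
reconstructions of any particular toolbox.

## Association and prediction statistics

- **Winsorization**: values beyond mean ± 3·IQR (linear-interpolation
  quantiles) are replaced by the nearer bound; applied to g and the
  global metrics before partial correlation, not to nodal predictors
  (which are standardized instead).
- **Covariate design** (fixed order): age, sex, age×sex, age², age²×sex,
  handedness, total brain volume, head motion. Age is mean-centered
  before powers/interactions purely for conditioning — the column span,
  and hence every residual, is unchanged.
- **Partial correlation test**: r of the two residual vectors;
  two-sided p from t = r√(df/(1−r²)) with df = n − 2 − n_controls. The
  df subtraction for the controls is documented here because
  conventions differ.
- **Holm correction** is applied over the family of global metrics
  within one data set (per-row of an association table), matching how
  such tables are reported; the family is whatever set of p-values the
  caller passes, so a whole-matrix family is equally expressible.
- **Elastic net**: objective (1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)
  with mixing α = 0.5; 100-value log-spaced λ grid from
  λ_max = max|Xᵀy|/(nα) down to 10⁻⁴λ_max; λ chosen by seeded 10-fold
  cross-validated MSE. `lambda_rule="min"` (default) takes the CV
  minimizer; `"1se"` the largest λ within one standard error of it —
  both are common extraction rules and the original choice is unstated.
  Outcome and predictors are residualized on the covariate design and
  standardized before fitting. The solver is scikit-learn's cyclic
  coordinate descent (tol 10⁻⁷).
- **Cross-sample prediction**: OLS of residualized g on the selected,
  residualized nodal metrics in the *target* cohort; R² and the overall
  F-test p are reported, with Bonferroni significance at 0.05/m. The
  default family m is the full prediction grid (sources × targets
  including self), i.e. 16 for a four-sample study. An alternative mode
  includes the controls as regressors instead of residualizing first;
  residualization is the default because selection used it. Empty
  predictor sets yield flagged placeholder rows rather than numbers.
- **Reliability**: ICC(3,1) is the two-way mixed-effects consistency
  form (BMS − EMS)/(BMS + (k−1)EMS) from the subjects × sessions ANOVA
  table, with no imputation of missing cells. Split-half reliability
  splits volumes into odd/even subsets, reruns connectivity → OMST →
  metrics on each half, correlates the half-derived metrics across
  subjects and applies Spearman–Brown SB = 2r/(1+r).
- **Handedness**: LQ = (R−L)/(R+L)×100 from ten-item inventory counts;
  code 1 iff LQ ≥ 60 (boundary inclusive).

## Synthetic cohorts

The generator produces everything the chain consumes, with a planted,
controllable g–metric association.

**Ground truth.** A modular block network: within-module weights around
`within_weight_mean` (default 0.5), between-module around
`between_weight_mean` (default 0.15), Gaussian jitter (SD 0.05),
clipped to (0, 0.999) since weights double as target correlations. With
probability `rewiring_prob` a within-module edge swaps weights with a
random between-module pair, creating strong long-range shortcuts
(small-world-like). If between-module weight is zero the modules are
bridged by single minimal edges carrying the weakest observed weight,
restoring connectivity. The default 376 nodes mirror a whole-brain
parcellation of 360 cortical plus 16 subcortical regions; tests and the
acceptance study use 16–40 nodes.

**Subject networks and drivers.** Each subject perturbs the ground
truth with two independent standard-normal latent drivers plus
per-edge log-normal noise (`noise_sd`, default 0.02): a *shape* driver
scaling within-module weights (default gain 0.12), which moves
clustering (invariant to uniform rescaling) while barely moving
efficiency, and a *scale* driver rescaling all weights (default SD
0.15), which moves efficiency while leaving max-normalized clustering
untouched. For clustering targets the shape driver carries the effect
and the scale driver supplies nuisance variance; for efficiency targets
the roles swap.

**Planting g.** The target metric is measured on each subject's network
through the default measurement chain itself (clip → Fisher z → OMST →
metric on the pruned graph), and

    g = true_r·z(metric) + motion_g_r·z(motion) + √(1 − true_r² − motion_g_r²)·ε,

standardized. Planting against the *measured* quantity — rather than
against a driver upstream of it — makes the planted correlation hold in
expectation for exactly the quantity the analysis reports, however
nonlinearly pruning transmits the drivers; across subjects the pruned
clustering and pruned efficiency are nearly uncorrelated under this
design, so no-effect metrics stay null. The `motion_g_r` term (default
−0.2) plants a negative g–head-motion association of the size reported
in cohorts where motion correlates with cognition, exercising the
motion covariate.

**BOLD simulation.** Node series are zero-mean Gaussian draws whose
target correlation matrix is the subject's weight matrix (unit
diagonal), repaired to the nearest positive definite correlation matrix
by Higham-style alternating projections (eigenvalue floor 10⁻⁸) when
needed; a failed repair is an internal error with diagnostics.
`n_confounds` AR(1) signals (φ = 0.3, unit stationary variance) are
added to every node with loadings U(0.1, 0.3) and returned as the
nuisance regressors, so confound control is testable: controlled
matrices have strictly weaker edges than uncontrolled ones on
confounded data. Per-subject head motion scales additional white noise,
coupling motion to measurement quality. No hemodynamic response,
spatial structure, or scanner artifacts are modeled.

**Demographics** are documented conveniences, not estimates of any real
sample: age ~ N(28.8, 3.7) clipped to [18, 40]; sex Bernoulli(½); right-
handers (85%) draw 8–10 right-hand inventory responses and others 0–7,
with LQ and the handedness code derived by the LQ rule (hence always
consistent); total brain volume ~ N(1250, 90) − 120·sex (ml); head
motion 0.1·exp(0.35·z), log-normal and strictly positive.

**Seeding.** All randomness flows from one integer seed through numpy
`SeedSequence` spawning in a fixed order (network jitter, subject
drivers, edge noise, demographics, g noise); the pipeline derives all
per-cohort and per-subject seeds from its master seed and echoes the
registry into the report, making runs bit-reproducible.

**What passing tests do not show.** The generator's Gaussianity,
stationarity, modular block structure, and independence of demographics
from network structure are idealizations; real BOLD has autocorrelated,
non-Gaussian signal, distance-dependent noise, and confounds correlated
with motion. Recovery of planted effects here validates the *code
path*, not the detectability of effects in real cohorts. Notably, when
the chain runs from short simulated scans, single-scan sampling noise
plus the discreteness of tree selection strongly attenuate clustering
effects — an emergent behavior consistent with the modest test–retest
reliability of clustering metrics reported on real data.

## Problem sizes and numerical choices

Test and acceptance workloads are scaled to desk hardware as package
choices: oracle-equivalence fixtures use n ≤ 15 nodes; OMST contract
checks 50 random 40-node matrices; statistical calibration uses 2000
null replicates at n = 300 and 20 elastic-net seeds at n = 500,
p = 100; the end-to-end recovery study uses two cohorts of 150 subjects
on 30-node networks over ten seeds per condition, with detection bars
fixed beforehand from a power analysis of this design (per-cohort Holm
power ≈ 0.9); reliability recovery uses n = 1000 subjects (ICC) and 25
subjects × up to 10⁴ volumes (split-half). Matrix symmetry is enforced
to 10⁻¹²  on containers and 10⁻⁸ on file ingest; OMST GCE ties break to
the earlier round; Dijkstra is exact, not heuristic.

## Known limitations

- Pairwise (not full-precision) partial correlations, by design.
- The lattice null's weight placement and the random null's rejection
  sampling follow one published convention among several; both are
  seeded and config-exposed but not toolbox-bit-identical.
- Elastic-net effect sizes are the coefficients at the selected λ, not
  refitted OLS betas.
- The pipeline's reliability block requires the time-series route; the
  direct-network route has no second session to correlate.
- No g-factor estimation, IQ norming, voxel-level processing, or
  anatomical handling: inputs begin at node time series or connectivity
  matrices.
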