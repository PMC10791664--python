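# fconn — graph-theoretical analysis of functional connectomes

`fconn` is a tested, reusable implementation of the full analysis chain used
in multi-center studies relating resting-state functional connectivity to
general intelligence (the *g* factor): connectome construction from regional
BOLD time series, data-driven topological filtering with orthogonal minimum
spanning trees (OMST), weighted graph metrics, and the association,
prediction, and reliability statistics built on top of them.

It is aimed at researchers in network neuroscience and individual-differences
psychology who want to run, audit, or stress-test this pipeline without
access to restricted imaging cohorts: a first-class synthetic-cohort module
generates BOLD-like multi-subject data with a *controlled* association
between *g* and any chosen graph property, so every stage — and the whole
chain end to end — is verifiable against planted ground truth.

## The analysis

**Connectivity.** For each subject, edge weights are pairwise partial
correlations between regional time courses, controlling nuisance (white
matter / ventricle) confound series. Negative correlations are set to zero
and the rest are Fisher z-transformed, giving a symmetric, nonnegative
weighted network with no self-connections (a 376-node parcellation has
376·375/2 = 70,500 unique edges).

**OMST filtering.** Instead of an arbitrary threshold, edge-disjoint minimum
spanning trees are extracted iteratively on distances d_ij = 1/w_ij and
aggregated while optimizing

> Global Cost Efficiency = E(selected)/E(original) − wiring cost,

where E is global efficiency and the wiring cost is the selected fraction of
total edge weight. The result is an individualized, sparse, *connected*
network.

**Graph metrics.** On the pruned network:

- global / nodal efficiency  E = (1/n) Σᵢ Eᵢ,  Eᵢ = Σ_{j≠i} (d_ij)⁻¹ / (n−1)
- global / local clustering  C = (1/n) Σᵢ Cᵢ,  Cᵢ = 2tᵢ / (kᵢ(kᵢ−1)) with
  geometric-mean triangle intensity tᵢ on max-normalized weights
- characteristic path length L_obs
- small-world propensity  φ = 1 − √((Δ_C² + Δ_L²)/2), locating C_obs and
  L_obs between matched lattice and random null networks

**Statistics.** Winsorization at mean ± 3 IQR; partial correlations of *g*
with the global metrics net of age, sex, age×sex, age², age²×sex, handedness,
total brain volume and head motion, Holm-corrected; elastic-net regression
(α = 0.5, 10-fold CV) selecting nodal predictors; cross-sample multiple
regression validating each predictor set in the other cohorts
(Bonferroni-corrected); predictor-set overlap; ICC(3,1) test–retest and
Spearman–Brown split-half reliability.

## Worked example

Simulate a two-cohort study with a planted correlation of 0.3 between *g*
and global clustering, run the full chain, and read the report (about half a
minute on one CPU):

```python
from fconn import PipelineConfig, run_pipeline

config = PipelineConfig(
    n_cohorts=2, n_subjects=100, n_nodes=30, n_modules=3,
    target_metric="global_clustering", true_r=0.3,
    from_time_series=False,      # analyze the subject networks directly
    run_reliability=False, seed=42,
)
report = run_pipeline(config)
for cohort, rows in report.associations.items():
    for row in rows:
        print(f"{cohort}  {row['metric']:<18}  r = {row['r']:+.3f}  "
              f"p_holm = {row['p_holm']:.4f}")
for p in report.predictions["local_clustering"]:
    if p["source"] != p["target"] and p["r_squared"] is not None:
        print(f"{p['source']} -> {p['target']}: R^2 = {p['r_squared']:.3f} "
              f"(p = {p['p_raw']:.4f}, {p['n_predictors']} predictors)")
```

```
cohort0  global_efficiency   r = -0.009  p_holm = 0.9303
cohort0  global_clustering   r = +0.415  p_holm = 0.0001
cohort1  global_efficiency   r = +0.092  p_holm = 0.3852
cohort1  global_clustering   r = +0.441  p_holm = 0.0000
cohort0 -> cohort1: R^2 = 0.258 (p = 0.0005, 8 predictors)
cohort1 -> cohort0: R^2 = 0.296 (p = 0.0013, 12 predictors)
```

The planted clustering effect is detected in both cohorts (positive,
Holm-significant) and cross-validates across cohorts, while the efficiency
association — no effect was planted on it — stays null. With
`from_time_series=True` the same chain runs from simulated BOLD series
(partial correlations controlling generated confounds); single-scan
measurement noise then attenuates the effect, mirroring the modest
test–retest reliability of clustering metrics on real scans.

A thin CLI mirrors the stages: `fconn simulate | connect | prune | metrics |
associate | select | predict | overlap | reliability | run-all`.

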