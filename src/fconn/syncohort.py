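"""Synthetic multi-subject cohorts with controllable g-metric effects.

Generates everything the downstream analysis consumes: a modular,
small-world-like ground-truth network; per-subject perturbed networks
whose chosen graph property correlates with a latent general-
intelligence score g at a planted level; BOLD-like multivariate Gaussian
time series with nuisance confounds and a head-motion noise covariate;
and a demographics table (age, sex, handedness LQ, total brain volume,
head motion).

Effect planting
    Two independent per-subject latent drivers perturb the network: a
    *shape* driver scales within-module weights relative to
    between-module weights (moving clustering, which is invariant to a
    uniform rescale of all weights under max-normalization), and a
    *scale* driver rescales all weights uniformly (moving efficiency,
    which is linear in 1/distance, while leaving clustering untouched).
    For a clustering target the shape driver is the effect carrier and
    the scale driver is nuisance variance; for an efficiency target the
    roles swap.  g is then built as

        g = true_r * z(metric) + motion_g_r * z(motion) + sqrt(1 - ...) * eps

    from the *realized* target metric of each subject's network,
    measured the way the analysis measures it (clipped correlations,
    Fisher z, OMST pruning, then the metric on the pruned graph), so the
    planted correlation holds for the quantity the pipeline reports, in
    expectation, regardless of how the drivers and edge noise propagate
    through pruning.

All randomness flows from one integer seed through numpy SeedSequence
spawning, in a fixed documented order (network jitter, subject drivers,
edge noise, demographics, g noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.correlation_tools import corr_nearest

from .assoc_stats import lateralization_quotient
from .connectome import fisher_z
from .containers import ConnectivityMatrix, TimeSeriesBundle, WeightedNetwork
from .graphmetrics import clustering, efficiency
from .omst import omst_filter

__all__ = [
    "GroundTruthSpec",
    "EffectSpec",
    "COHORT_COLUMNS",
    "TARGET_METRICS",
    "generate_ground_truth_network",
    "generate_cohort",
    "simulate_bold",
    "export_cohort",
]

#: fixed cohort-table header, in this column order
COHORT_COLUMNS = (
    "id",
    "g",
    "age",
    "sex",
    "LQ",
    "handedness",
    "total_brain_volume",
    "head_motion",
)

TARGET_METRICS = (
    "global_efficiency",
    "global_clustering",
    "nodal_efficiency",
    "local_clustering",
)

_MAX_WEIGHT = 0.999  # weights double as target correlations downstream


@dataclass(frozen=True)
class GroundTruthSpec:
    """Ground-truth network parameters.

    The default node count matches a whole-brain parcellation with 360
    cortical plus 16 subcortical regions; tests use far smaller graphs.
    """

    n_nodes: int = 376
    n_modules: int = 8
    within_weight_mean: float = 0.5
    between_weight_mean: float = 0.15
    rewiring_prob: float = 0.05
    weight_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if not 1 <= self.n_modules <= self.n_nodes:
            raise ValueError("need 1 <= n_modules <= n_nodes")
        if not 0.0 < self.within_weight_mean < 1.0:
            raise ValueError("within_weight_mean must lie in (0, 1)")
        if not 0.0 <= self.between_weight_mean < 1.0:
            raise ValueError("between_weight_mean must lie in [0, 1)")
        if self.within_weight_mean <= self.between_weight_mean:
            raise ValueError("within_weight_mean must exceed between_weight_mean")
        if not 0.0 <= self.rewiring_prob <= 1.0:
            raise ValueError("rewiring_prob must be a probability")
        if self.weight_jitter_sd < 0:
            raise ValueError("weight_jitter_sd must be nonnegative")


@dataclass(frozen=True)
class EffectSpec:
    """Planted g-metric association.

    ``true_r`` is the target correlation between g and the subject-level
    target metric; ``noise_sd`` is the per-edge multiplicative
    (log-scale) noise of subject networks; ``driver_gain`` and
    ``scale_sd`` set how strongly the latent shape and scale drivers
    move the weights; ``motion_g_r`` plants a negative association
    between g and head motion (mimicking cohorts where motion correlates
    with cognition).
    """

    target_metric: str = "global_clustering"
    target_nodes: tuple[int, ...] = ()
    true_r: float = 0.3
    noise_sd: float = 0.02
    driver_gain: float = 0.12
    scale_sd: float = 0.15
    motion_g_r: float = -0.2

    def __post_init__(self) -> None:
        if self.target_metric not in TARGET_METRICS:
            raise ValueError(f"target_metric must be one of {TARGET_METRICS}")
        if abs(self.true_r) > 1.0:
            raise ValueError("|true_r| must not exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.true_r**2 + self.motion_g_r**2 > 1.0:
            raise ValueError("true_r^2 + motion_g_r^2 must not exceed 1")
        nodal = self.target_metric in ("nodal_efficiency", "local_clustering")
        if nodal and not self.target_nodes:
            raise ValueError("nodal targets require target_nodes")
        if not nodal and self.target_nodes:
            raise ValueError("global targets take no target_nodes")


def module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Deterministic near-equal partition of nodes into modules."""
    return np.concatenate(
        [np.full(len(chunk), m) for m, chunk in enumerate(np.array_split(np.arange(n_nodes), n_modules))]
    )


def generate_ground_truth_network(spec: GroundTruthSpec) -> WeightedNetwork:
    """Modular block-structured weighted network with optional rewiring.

    Within-module pairs get strong weights, between-module pairs weak
    ones (exactly zero when ``between_weight_mean`` is 0); with
    probability ``rewiring_prob`` a within-module edge swaps weights
    with a random between-module pair, creating strong long-range
    shortcuts.  If the result is disconnected (possible when between
    weights are zero), minimal bridge edges are added to restore
    connectivity.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    modules = module_assignment(n, spec.n_modules)
    same = modules[:, None] == modules[None, :]
    means = np.where(same, spec.within_weight_mean, spec.between_weight_mean)

    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mu = means[iu]
    jitter = rng.normal(0.0, spec.weight_jitter_sd, size=mu.shape)
    vals = np.where(mu > 0, np.clip(mu + jitter, 1e-3, _MAX_WEIGHT), 0.0)

    # rewire: swap within-module weights onto random between-module pairs
    within_idx = np.flatnonzero(same[iu])
    between_idx = np.flatnonzero(~same[iu])
    if spec.rewiring_prob > 0 and between_idx.size and within_idx.size:
        to_rewire = within_idx[rng.random(within_idx.size) < spec.rewiring_prob]
        targets = rng.choice(between_idx, size=to_rewire.size, replace=False) if to_rewire.size <= between_idx.size else between_idx
        for a, b in zip(to_rewire, targets[: to_rewire.size]):
            vals[a], vals[b] = vals[b], vals[a]

    w[iu] = vals
    w = w + w.T
    w = _bridge_components(w)
    return WeightedNetwork(w)


def _bridge_components(w: np.ndarray) -> np.ndarray:
    """Add one weak edge per extra component to make the graph connected."""
    w = w.copy()
    n_comp, labels = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp <= 1:
        return w
    positive = w[w > 0]
    bridge_weight = float(positive.min()) if positive.size else 0.1
    anchors = [int(np.flatnonzero(labels == c)[0]) for c in range(n_comp)]
    for other in anchors[1:]:
        w[anchors[0], other] = w[other, anchors[0]] = bridge_weight
    return w


def _target_metric_value(w: np.ndarray, espec: EffectSpec, max_trees: int = 50) -> float:
    """Target metric under the default measurement chain.

    Subject networks are read the way the analysis reads them — clipped
    correlations, Fisher z, OMST pruning — and the metric is taken on
    the pruned graph, so a correlation planted against this value holds
    for the quantity the pipeline actually measures.
    """
    pruned = omst_filter(
        fisher_z(ConnectivityMatrix(w, stage="clipped")), max_trees=max_trees
    ).network.weights
    if espec.target_metric == "global_efficiency":
        return efficiency(pruned)[0]
    if espec.target_metric == "global_clustering":
        return clustering(pruned)[0]
    if espec.target_metric == "nodal_efficiency":
        return float(efficiency(pruned)[1][list(espec.target_nodes)].mean())
    return float(clustering(pruned)[1][list(espec.target_nodes)].mean())


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_cohort(
    n_subjects: int,
    gspec: GroundTruthSpec,
    espec: EffectSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[WeightedNetwork]]:
    """Generate a cohort table and per-subject networks with a planted effect.

    Returns a DataFrame with columns :data:`COHORT_COLUMNS` and one
    perturbed :class:`WeightedNetwork` per subject.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    ss = np.random.SeedSequence(seed)
    rng_net, rng_drv, rng_noise, rng_demo, rng_g = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    del rng_net  # reserved slot: the ground truth uses gspec.seed

    w0 = generate_ground_truth_network(gspec).weights
    n = w0.shape[0]
    modules = module_assignment(n, gspec.n_modules)
    same = modules[:, None] == modules[None, :]
    np.fill_diagonal(same, False)

    nodal = espec.target_metric in ("nodal_efficiency", "local_clustering")
    if nodal:
        bad = [i for i in espec.target_nodes if not 0 <= i < n]
        if bad:
            raise ValueError(f"target_nodes out of range: {bad}")
        incident = np.zeros((n, n), dtype=bool)
        incident[list(espec.target_nodes), :] = True
        incident = incident | incident.T
        np.fill_diagonal(incident, False)
    else:
        incident = np.ones((n, n), dtype=bool)
        np.fill_diagonal(incident, False)

    clustering_target = espec.target_metric in ("global_clustering", "local_clustering")
    shape_mask = same & incident  # within-module edges (possibly node-restricted)
    scale_mask = incident  # uniform over all (possibly node-restricted) edges

    u = rng_drv.standard_normal(n_subjects)  # effect carrier
    v = rng_drv.standard_normal(n_subjects)  # nuisance driver
    if clustering_target:
        effect_mask, nuis_mask = shape_mask, np.ones_like(scale_mask) & ~np.eye(n, dtype=bool)
    else:
        effect_mask, nuis_mask = scale_mask, shape_mask

    iu = np.triu_indices(n, k=1)
    networks: list[WeightedNetwork] = []
    metric_vals = np.empty(n_subjects)
    for s in range(n_subjects):
        factors = np.ones((n, n))
        factors[effect_mask] *= 1.0 + espec.driver_gain * u[s]
        factors[nuis_mask] *= 1.0 + espec.scale_sd * v[s]
        noise = np.zeros((n, n))
        noise[iu] = rng_noise.normal(0.0, espec.noise_sd, size=iu[0].shape)
        noise = noise + noise.T
        w = np.clip(w0 * factors * np.exp(noise), 0.0, _MAX_WEIGHT)
        w[w0 == 0] = 0.0
        net = WeightedNetwork(w)
        networks.append(net)
        metric_vals[s] = _target_metric_value(net.weights, espec)

    # demographics (documented convenience distributions, not estimates
    # of any real sample)
    age = np.clip(rng_demo.normal(28.8, 3.7, n_subjects), 18.0, 40.0)
    sex = rng_demo.integers(0, 2, n_subjects)
    is_right = rng_demo.random(n_subjects) < 0.85
    r_counts = np.where(is_right, rng_demo.integers(8, 11, n_subjects), rng_demo.integers(0, 8, n_subjects))
    lq = np.empty(n_subjects)
    hand = np.empty(n_subjects, dtype=int)
    for s in range(n_subjects):
        lq[s], hand[s] = lateralization_quotient(int(r_counts[s]), 10 - int(r_counts[s]))
    tbv = rng_demo.normal(1250.0, 90.0, n_subjects) - 120.0 * sex
    z_motion = rng_demo.standard_normal(n_subjects)
    head_motion = 0.1 * np.exp(0.35 * z_motion)

    resid_var = 1.0 - espec.true_r**2 - espec.motion_g_r**2
    g = (
        espec.true_r * _zscore(metric_vals)
        + espec.motion_g_r * _zscore(z_motion)
        + np.sqrt(max(resid_var, 0.0)) * rng_g.standard_normal(n_subjects)
    )
    g = _zscore(g)

    table = pd.DataFrame(
        {
            "id": [f"sub-{s:04d}" for s in range(n_subjects)],
            "g": g,
            "age": age,
            "sex": sex,
            "LQ": lq,
            "handedness": hand,
            "total_brain_volume": tbv,
            "head_motion": head_motion,
        }
    )
    # realized target metric per subject (diagnostic; not part of the
    # written cohort table)
    table.attrs["target_metric_value"] = metric_vals
    return table, networks


# ---------------------------------------------------------------------------
# BOLD-like time series
# ---------------------------------------------------------------------------

_AR_PHI = 0.3  # confound autocorrelation
_LOADING_RANGE = (0.1, 0.3)


def simulate_bold(
    network: WeightedNetwork,
    n_volumes: int,
    tr_seconds: float = 0.72,
    n_confounds: int = 0,
    motion_scale: float = 0.0,
    seed: int = 0,
    subject_id: str = "sub-00",
    session_id: str = "ses-01",
) -> TimeSeriesBundle:
    """Zero-mean Gaussian node series with network-derived correlations.

    Edge weights are read as target correlations; the target matrix is
    repaired to the nearest positive definite correlation matrix
    (Higham-style alternating projections, tolerance 1e-8) before
    sampling.  ``n_confounds`` AR(1) nuisance signals (phi = 0.3) are
    added to every node with loadings drawn U(0.1, 0.3), and returned so
    confound control is testable.  ``motion_scale`` adds white noise of
    that amplitude, emulating motion-corrupted scans.
    """
    if n_volumes < 10:
        raise ValueError("n_volumes must be at least 10")
    if motion_scale < 0 or n_confounds < 0:
        raise ValueError("motion_scale and n_confounds must be nonnegative")
    rng = np.random.default_rng(seed)
    n = network.n_nodes

    target = network.weights.copy()
    np.fill_diagonal(target, 1.0)
    eig_min = float(np.linalg.eigvalsh(target).min())
    if eig_min < 1e-8:
        with warnings.catch_warnings():
            # corr_nearest reaches the 1e-8 floor and then reports its
            # iteration cap; the post-check below is what matters
            warnings.simplefilter("ignore")
            target = corr_nearest(target, threshold=1e-8, n_fact=10)
        eig_min = float(np.linalg.eigvalsh(target).min())
        if eig_min < -1e-8:
            raise RuntimeError(
                f"nearest-PD repair failed: minimum eigenvalue {eig_min:.3e} "
                f"for a {n}-node target correlation matrix"
            )
    chol = np.linalg.cholesky(target + 1e-10 * np.eye(n))
    x = chol @ rng.standard_normal((n, n_volumes))

    confounds = np.empty((n_confounds, n_volumes))
    for c in range(n_confounds):
        innov = rng.standard_normal(n_volumes) * np.sqrt(1.0 - _AR_PHI**2)
        confounds[c] = lfilter([1.0], [1.0, -_AR_PHI], innov)
    if n_confounds:
        loadings = rng.uniform(*_LOADING_RANGE, size=(n, n_confounds))
        x = x + loadings @ confounds
    if motion_scale > 0:
        x = x + motion_scale * rng.standard_normal((n, n_volumes))

    return TimeSeriesBundle(
        node_series=x,
        confound_series=confounds,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        session_id=session_id,
        seed=seed,
    )


def export_cohort(
    out_dir,
    table: pd.DataFrame,
    bundles: list[TimeSeriesBundle] | None = None,
    spec_echo: dict | None = None,
    seed: int | None = None,
):
    """Write a cohort to disk: cohort CSV, per-subject TSV series, manifest JSON."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = out / "cohort.csv"
    table[list(COHORT_COLUMNS)].to_csv(cohort_path, index=False)
    entries = []
    if bundles is not None:
        for b in bundles:
            node_path = out / f"{b.subject_id}_{b.session_id}_nodes.tsv"
            conf_path = out / f"{b.subject_id}_{b.session_id}_confounds.tsv"
            np.savetxt(node_path, b.node_series, delimiter="\t")
            np.savetxt(conf_path, b.confound_series, delimiter="\t")
            entries.append(
                {
                    "subject_id": b.subject_id,
                    "session_id": b.session_id,
                    "nodes": node_path.name,
                    "confounds": conf_path.name,
                    "tr_seconds": b.tr_seconds,
                }
            )
    manifest = {
        "cohort": cohort_path.name,
        "series": entries,
        "seed": seed,
        "spec": spec_echo or {},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out / "manifest.json"
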