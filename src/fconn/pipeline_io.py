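"""Pipeline orchestration, configuration, and text-based file formats.

Runs the full analysis in fixed order — simulate or ingest, build
connectivity, OMST-prune, compute graph metrics, associate with g,
select and cross-validate nodal predictors, assess reliability — and
emits a reproducible report that echoes its configuration, a hash of
it, and every seed used.

Formats: square TSV for matrices (header row and index column of node
labels, stage recorded in a sidecar JSON), CSV with a fixed header for
cohort tables, JSON for reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc_stats import (
    AssociationResult,
    CovariateDesign,
    cross_sample_predict,
    elastic_net_select,
    holm_adjust,
    icc_3_1,
    partial_correlation_test,
    predictor_overlap,
    split_half_reliability,
    winsorize,
)
from .connectome import build_connectivity
from .containers import ConnectivityMatrix, WeightedNetwork
from .graphmetrics import clustering, efficiency, small_world_propensity
from .omst import omst_filter
from .syncohort import (
    COHORT_COLUMNS,
    EffectSpec,
    GroundTruthSpec,
    generate_cohort,
    simulate_bold,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "AnalysisReport",
    "run_pipeline",
    "read_matrix",
    "write_matrix",
    "read_cohort",
    "write_cohort",
]

logger = logging.getLogger("fconn")

_ASYM_TOL = 1e-8


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str, subject: str | None = None):
        self.stage = stage
        self.subject = subject
        where = f"stage '{stage}'" + (f", subject {subject}" if subject else "")
        super().__init__(f"pipeline failed at {where}: {detail}")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of a synthetic two-cohort analysis run.

    Unknown keys are rejected by :meth:`from_dict`; the whole config is
    echoed (and hashed) into the report.
    """

    # cohorts and ground truth
    n_cohorts: int = 2
    n_subjects: int = 60
    n_nodes: int = 40
    n_modules: int = 4
    within_weight_mean: float = 0.5
    between_weight_mean: float = 0.15
    rewiring_prob: float = 0.05
    weight_jitter_sd: float = 0.05
    # planted effect
    target_metric: str = "global_clustering"
    target_nodes: tuple[int, ...] = ()
    true_r: float = 0.3
    noise_sd: float = 0.02
    driver_gain: float = 0.12
    scale_sd: float = 0.15
    motion_g_r: float = -0.2
    # connectivity construction
    from_time_series: bool = True
    n_volumes: int = 200
    tr_seconds: float = 0.72
    n_confounds: int = 3
    motion_noise_gain: float = 1.0
    clip_before_z: bool = True
    # pruning and metrics
    max_trees: int = 50
    compute_swp: bool = False
    n_null: int = 10
    # statistics
    lambda_rule: str = "min"
    #: Bonferroni family size for the prediction grid; None means the
    #: grid size n_cohorts^2 (sources x targets including self), the
    #: same convention that gives 16 for a four-sample study
    bonferroni_m: int | None = None
    prediction_mode: str = "residualized"
    # reliability
    run_reliability: bool = True
    run_split_half: bool = False
    # bookkeeping
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be at least 1")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.prediction_mode not in ("residualized", "covariates_in_model"):
            raise ValueError("unknown prediction_mode")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "target_nodes" in data:
            data = {**data, "target_nodes": tuple(data["target_nodes"])}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_nodes"] = list(d["target_nodes"])
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All results of one pipeline run, JSON-serializable."""

    config: dict
    config_hash: str
    version: str
    seed_registry: dict
    associations: dict = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    reliability: list = field(default_factory=list)
    gce_diagnostics: dict = field(default_factory=dict)
    cohorts: dict = field(default_factory=dict)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=indent, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _cohort_seed_registry(cfg: PipelineConfig) -> dict:
    """Derive all seeds from the master seed, in a fixed documented order."""
    rng = np.random.default_rng(cfg.seed)
    registry: dict = {"master": cfg.seed, "cohorts": []}
    for c in range(cfg.n_cohorts):
        entry = {
            "name": f"cohort{c}",
            "ground_truth": int(rng.integers(2**31 - 1)),
            "cohort": int(rng.integers(2**31 - 1)),
            "bold": [int(s) for s in rng.integers(2**31 - 1, size=cfg.n_subjects * 2)],
            "swp": int(rng.integers(2**31 - 1)),
            "enet": int(rng.integers(2**31 - 1)),
        }
        registry["cohorts"].append(entry)
    return registry


def _analyze_cohort(cfg: PipelineConfig, entry: dict) -> dict:
    """Simulate one cohort and carry every subject through metrics."""
    gspec = GroundTruthSpec(
        n_nodes=cfg.n_nodes,
        n_modules=cfg.n_modules,
        within_weight_mean=cfg.within_weight_mean,
        between_weight_mean=cfg.between_weight_mean,
        rewiring_prob=cfg.rewiring_prob,
        weight_jitter_sd=cfg.weight_jitter_sd,
        seed=entry["ground_truth"],
    )
    espec = EffectSpec(
        target_metric=cfg.target_metric,
        target_nodes=cfg.target_nodes,
        true_r=cfg.true_r,
        noise_sd=cfg.noise_sd,
        driver_gain=cfg.driver_gain,
        scale_sd=cfg.scale_sd,
        motion_g_r=cfg.motion_g_r,
    )
    table, networks = generate_cohort(cfg.n_subjects, gspec, espec, seed=entry["cohort"])

    sessions: dict[int, list] = {0: [], 1: []}  # session -> per-subject metric rows
    nodal_e: list[np.ndarray] = []
    nodal_c: list[np.ndarray] = []
    n_trees, costs = [], []
    bundles_ses1 = []
    n_sessions = 2 if (cfg.run_reliability and cfg.from_time_series) else 1

    for s, net in enumerate(networks):
        for ses in range(n_sessions):
            subject = table["id"].iloc[s]
            try:
                if cfg.from_time_series:
                    bundle = simulate_bold(
                        net,
                        n_volumes=cfg.n_volumes,
                        tr_seconds=cfg.tr_seconds,
                        n_confounds=cfg.n_confounds,
                        motion_scale=cfg.motion_noise_gain * float(table["head_motion"].iloc[s]),
                        seed=entry["bold"][2 * s + ses],
                        subject_id=subject,
                        session_id=f"ses-{ses + 1:02d}",
                    )
                    if ses == 0:
                        bundles_ses1.append(bundle)
                    conn = build_connectivity(bundle, clip_before_z=cfg.clip_before_z)
                else:
                    clipped = ConnectivityMatrix(net.weights, stage="clipped")
                    from .connectome import fisher_z

                    conn = fisher_z(clipped)
                pruned = omst_filter(conn, max_trees=cfg.max_trees)
                e, e_i = efficiency(pruned.network)
                c, c_i = clustering(pruned.network)
                row = {"global_efficiency": e, "global_clustering": c}
                if cfg.compute_swp:
                    row["small_world_propensity"] = small_world_propensity(
                        pruned.network, n_null=cfg.n_null, seed=entry["swp"] + s
                    ).phi
                sessions[ses].append(row)
                if ses == 0:
                    nodal_e.append(e_i)
                    nodal_c.append(c_i)
                    n_trees.append(pruned.n_trees)
                    costs.append(pruned.wiring_cost)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineError("metrics", str(exc), subject=subject) from exc

    globals_df = pd.DataFrame(sessions[0])
    out = {
        "table": table,
        "globals": globals_df,
        "globals_ses2": pd.DataFrame(sessions[1]) if sessions[1] else None,
        "nodal_efficiency": np.vstack(nodal_e),
        "local_clustering": np.vstack(nodal_c),
        "bundles_ses1": bundles_ses1,
        "diag": {
            "mean_n_trees": float(np.mean(n_trees)),
            "mean_wiring_cost": float(np.mean(costs)),
        },
    }
    return out


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full synthetic analysis and return the report.

    Stage order: cohort simulation -> connectivity -> OMST pruning ->
    graph metrics -> winsorized, Holm-corrected partial correlations ->
    elastic-net selection -> cross-sample prediction and overlap ->
    test-retest / split-half reliability.
    """
    registry = _cohort_seed_registry(config)
    report = AnalysisReport(
        config=config.to_dict(),
        config_hash=config.config_hash,
        version=__version__,
        seed_registry=registry,
    )
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    try:
        cohorts = {}
        for entry in registry["cohorts"]:
            logger.info("simulating and analyzing %s", entry["name"])
            cohorts[entry["name"]] = _analyze_cohort(config, entry)

        # associations: winsorize g and global metrics, Holm over the family
        for name, data in cohorts.items():
            table, globals_df = data["table"], data["globals"]
            design = CovariateDesign.from_cohort(table)
            g_w = winsorize(table["g"].to_numpy())
            results: list[AssociationResult] = []
            for metric in globals_df.columns:
                m_w = winsorize(globals_df[metric].to_numpy())
                r, p = partial_correlation_test(g_w, m_w, design)
                results.append(AssociationResult(metric=metric, r=r, p_raw=p))
            adj = holm_adjust(np.array([res.p_raw for res in results]))
            for res, p_h in zip(results, adj):
                res.p_holm = float(p_h)
            report.associations[name] = [dataclasses.asdict(res) for res in results]
            report.gce_diagnostics[name] = data["diag"]
            report.cohorts[name] = {"n_subjects": len(table)}

        # elastic net + cross-sample prediction + overlap, per nodal family
        for family in ("nodal_efficiency", "local_clustering"):
            models = {}
            for entry in registry["cohorts"]:
                name = entry["name"]
                data = cohorts[name]
                design = CovariateDesign.from_cohort(data["table"])
                models[name] = elastic_net_select(
                    data[family],
                    data["table"]["g"].to_numpy(),
                    design=design,
                    seed=entry["enet"],
                    lambda_rule=config.lambda_rule,
                )
            grid = []
            for source, model in models.items():
                for target, data in cohorts.items():
                    design = CovariateDesign.from_cohort(data["table"])
                    pred = cross_sample_predict(
                        model.selected,
                        source,
                        target,
                        data["table"]["g"].to_numpy(),
                        data[family],
                        design,
                        bonferroni_m=config.bonferroni_m or config.n_cohorts**2,
                        mode=config.prediction_mode,
                    )
                    grid.append(dataclasses.asdict(pred))
            report.predictions[family] = grid
            if len(models) >= 2:
                supports = {k: set(int(i) for i in m.selected) for k, m in models.items()}
                effects = {
                    k: {int(i): float(m.beta[i]) for i in m.selected} for k, m in models.items()
                }
                report.overlap[family] = predictor_overlap(supports, effects)

        # reliability
        if config.run_reliability and config.from_time_series:
            rel_rows = []
            for name, data in cohorts.items():
                if data["globals_ses2"] is None:
                    continue
                for metric in data["globals"].columns:
                    m = np.column_stack(
                        [data["globals"][metric], data["globals_ses2"][metric]]
                    )
                    rel_rows.append(
                        {"cohort": name, "metric": metric, "kind": "icc_3_1", "value": icc_3_1(m)}
                    )
                if config.run_split_half:
                    sh = split_half_reliability(
                        data["bundles_ses1"],
                        max_trees=config.max_trees,
                        clip_before_z=config.clip_before_z,
                    )
                    for _, row in sh.iterrows():
                        rel_rows.append(
                            {
                                "cohort": name,
                                "metric": row["metric"],
                                "kind": "split_half_sb",
                                "value": float(row["sb"]),
                            }
                        )
            report.reliability = rel_rows
    except PipelineError as err:
        if out_dir:
            failed = out_dir / "failed"
            failed.mkdir(exist_ok=True)
            report.to_json(failed / "report_partial.json")
        raise err

    if out_dir:
        report.to_json(out_dir / "report.json")
        for name in report.associations:
            pd.DataFrame(report.associations[name]).to_csv(
                out_dir / f"associations_{name}.csv", index=False
            )
        for family, grid in report.predictions.items():
            pd.DataFrame(grid).to_csv(out_dir / f"predictions_{family}.csv", index=False)
        if report.reliability:
            pd.DataFrame(report.reliability).to_csv(out_dir / "reliability.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------


def write_matrix(path, matrix: WeightedNetwork | ConnectivityMatrix) -> Path:
    """Write a square matrix as TSV with node labels; stage to a sidecar JSON."""
    path = Path(path)
    if isinstance(matrix, ConnectivityMatrix):
        values, stage = matrix.values, matrix.stage
        labels = matrix.labels or [f"node{i:03d}" for i in range(matrix.n_nodes)]
    else:
        values, stage = matrix.weights, None
        labels = matrix.node_labels()
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.12g")
    if stage is not None:
        Path(str(path) + ".json").write_text(json.dumps({"stage": stage}))
    return path


def read_matrix(path) -> WeightedNetwork | ConnectivityMatrix:
    """Read a square TSV matrix; validates labels, symmetry, and finiteness.

    Returns a :class:`ConnectivityMatrix` when a stage sidecar exists or
    negative entries are present (stage ``raw_r``), otherwise a
    :class:`WeightedNetwork`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path.name}: matrix is not square {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path.name}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path.name}: NaN at row '{df.index[i]}' (line {i + 2}), column '{df.columns[j]}'"
        )
    asym = float(np.max(np.abs(values - values.T)))
    if asym > _ASYM_TOL:
        raise ValueError(f"{path.name}: asymmetry {asym:.3e} exceeds {_ASYM_TOL:.0e}")
    values = (values + values.T) / 2.0
    labels = [str(x) for x in df.index]
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        stage = json.loads(sidecar.read_text())["stage"]
        return ConnectivityMatrix(values, stage=stage, labels=labels)
    if np.any(values < 0):
        return ConnectivityMatrix(values, stage="raw_r", labels=labels)
    return WeightedNetwork(values, labels=labels)


def write_cohort(path, table: pd.DataFrame) -> Path:
    """Write a cohort table as CSV with the fixed documented header."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    path = Path(path)
    table[list(COHORT_COLUMNS)].to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; validates the header and LQ/handedness coding."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path.name}: empty cohort file") from exc
    if table.empty:
        raise ValueError(f"{path.name}: cohort table has no rows")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    expected = (table["LQ"].to_numpy(float) >= 60.0).astype(int)
    actual = table["handedness"].to_numpy(int)
    bad = np.flatnonzero(expected != actual)
    if bad.size:
        ids = table["id"].iloc[bad].tolist()
        warnings.warn(
            f"handedness coding inconsistent with the LQ >= 60 rule for rows: {ids}",
            UserWarning,
            stacklevel=2,
        )
    return table
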