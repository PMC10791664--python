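"""Association, prediction, and reliability statistics.

The statistical battery relating a latent general-intelligence score g
to graph metrics: IQR-based winsorization, covariate residualization,
Holm-corrected partial correlations for the three global metrics,
elastic-net selection of nodal predictors (mixing parameter alpha = 0.5,
10-fold cross-validation), cross-sample multiple-regression validation
with Bonferroni correction, predictor-set overlap, ICC(3,1) test-retest
reliability, and split-half reliability with the Spearman-Brown
correction.

Covariate set (fixed order): age, sex, age*sex, age^2, age^2*sex,
handedness, total brain volume, head motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .connectome import build_connectivity
from .containers import TimeSeriesBundle
from .graphmetrics import clustering, efficiency
from .omst import omst_filter

__all__ = [
    "COVARIATE_COLUMNS",
    "CovariateDesign",
    "AssociationResult",
    "ElasticNetModel",
    "PredictionResult",
    "winsorize",
    "residualize",
    "partial_correlation_test",
    "holm_adjust",
    "bonferroni_threshold",
    "significant_effect_summary",
    "elastic_net_select",
    "cross_sample_predict",
    "predictor_overlap",
    "icc_3_1",
    "spearman_brown",
    "split_half_reliability",
    "lateralization_quotient",
]

COVARIATE_COLUMNS = (
    "age",
    "sex",
    "age_x_sex",
    "age_sq",
    "age_sq_x_sex",
    "handedness",
    "total_brain_volume",
    "head_motion",
)


@dataclass
class CovariateDesign:
    """Control-variable design matrix in the fixed documented order.

    Age is mean-centered before the polynomial and interaction terms are
    formed; this changes nothing statistically (the column span is
    identical) but keeps the condition number manageable.
    """

    matrix: np.ndarray
    names: tuple[str, ...] = COVARIATE_COLUMNS
    intercept: bool = True

    @classmethod
    def from_cohort(cls, table: pd.DataFrame) -> "CovariateDesign":
        required = ["age", "sex", "handedness", "total_brain_volume", "head_motion"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        age = table["age"].to_numpy(float)
        age_c = age - age.mean()
        sex = table["sex"].to_numpy(float)
        cols = np.column_stack(
            [
                age_c,
                sex,
                age_c * sex,
                age_c**2,
                age_c**2 * sex,
                table["handedness"].to_numpy(float),
                table["total_brain_volume"].to_numpy(float),
                table["head_motion"].to_numpy(float),
            ]
        )
        return cls(matrix=cols)

    @property
    def n_controls(self) -> int:
        return self.matrix.shape[1]

    @property
    def condition_number(self) -> float:
        x = self.matrix - self.matrix.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        return float(np.linalg.cond(x / sd))

    def with_intercept(self) -> np.ndarray:
        n = self.matrix.shape[0]
        if self.intercept:
            return np.column_stack([np.ones(n), self.matrix])
        return self.matrix


@dataclass
class AssociationResult:
    metric: str
    r: float
    p_raw: float
    p_holm: float | None = None


@dataclass
class ElasticNetModel:
    alpha: float
    lambda_grid: np.ndarray
    lambda_selected: float
    beta: np.ndarray
    selected: np.ndarray
    cv_folds: int
    seed: int
    lambda_rule: str = "min"


@dataclass
class PredictionResult:
    source: str
    target: str
    n_predictors: int
    r_squared: float | None
    p_raw: float | None
    significant_bonferroni: bool
    note: str = ""


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def winsorize(values: np.ndarray) -> np.ndarray:
    """Replace values beyond mean +/- 3 IQR by the nearer bound.

    IQR uses linear-interpolation quantiles; an all-identical vector
    (IQR 0) is returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("winsorization needs at least 4 values")
    if np.any(~np.isfinite(x)):
        raise ValueError("winsorization requires finite values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    if iqr == 0.0:
        return x.copy()
    lo, hi = x.mean() - 3.0 * iqr, x.mean() + 3.0 * iqr
    return np.clip(x, lo, hi)


def _find_dependent_columns(design: np.ndarray, names: tuple[str, ...]) -> list[str]:
    kept: list[int] = []
    dependent: list[str] = []
    for j in range(design.shape[1]):
        trial = design[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            dependent.append(names[j] if j < len(names) else f"col{j}")
    return dependent


def residualize(y: np.ndarray, design: CovariateDesign) -> np.ndarray:
    """OLS residuals of y on the control design (with intercept)."""
    y = np.asarray(y, dtype=float)
    x = design.with_intercept()
    if y.shape[0] != x.shape[0]:
        raise ValueError("y and design have different lengths")
    if y.shape[0] <= x.shape[1] + 1:
        raise ValueError("too few observations for the design")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        dep = _find_dependent_columns(x[:, 1:], design.names)
        raise ValueError(f"rank-deficient design; dependent columns: {dep}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_correlation_test(
    g: np.ndarray,
    metric: np.ndarray,
    design: CovariateDesign,
) -> tuple[float, float]:
    """Partial correlation of g and a metric net of the control design.

    r is the Pearson correlation of the two residual vectors; the
    two-sided p-value comes from t = r * sqrt(df / (1 - r^2)) with
    df = n - 2 - n_controls.
    """
    rg = residualize(np.asarray(g, float), design)
    rm = residualize(np.asarray(metric, float), design)
    if rg.std() == 0 or rm.std() == 0:
        raise ValueError("zero-variance residuals: correlation undefined")
    n = rg.shape[0]
    df = n - 2 - design.n_controls
    if df <= 0:
        raise ValueError(f"nonpositive degrees of freedom (n={n}, controls={design.n_controls})")
    r = float(np.corrcoef(rg, rm)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * st.t.sf(abs(t), df)
    return r, float(p)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 16) -> float:
    """Per-test significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def significant_effect_summary(
    results: list[AssociationResult] | list[tuple[float, float]],
    alpha: float = 0.05,
) -> tuple[float, float, int]:
    """Mean and sample SD of effect sizes with p below alpha.

    Accepts AssociationResult objects or bare (r, p) pairs; uses the raw
    per-test p-values, mirroring a table whose boldface marks p < alpha.
    Returns (mean_r, sd_r, n_significant).
    """
    pairs = [
        (res.r, res.p_raw) if isinstance(res, AssociationResult) else (res[0], res[1])
        for res in results
    ]
    sig = np.array([r for r, p in pairs if p < alpha])
    if sig.size == 0:
        return float("nan"), float("nan"), 0
    sd = float(sig.std(ddof=1)) if sig.size > 1 else 0.0
    return float(sig.mean()), sd, int(sig.size)


# ---------------------------------------------------------------------------
# elastic net and cross-sample validation
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def elastic_net_select(
    X: np.ndarray,
    g: np.ndarray,
    design: CovariateDesign | None = None,
    seed: int = 0,
    alpha: float = 0.5,
    cv_folds: int = 10,
    n_lambda: int = 100,
    lambda_rule: str = "min",
) -> ElasticNetModel:
    """Elastic-net selection of nodal predictors of g.

    Minimizes (1/2n)||y - Xb||^2 + lambda * (alpha*||b||_1 +
    (1-alpha)/2*||b||_2^2) over a 100-value log-spaced lambda grid from
    lambda_max = max|X'y|/(n*alpha) down to 1e-4*lambda_max, choosing
    lambda by seeded 10-fold cross-validated MSE.  ``lambda_rule`` is
    "min" (CV minimizer) or "1se" (largest lambda within one standard
    error of the minimum).  If a design is given, y and every column of
    X are first residualized on it and standardized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(g, dtype=float)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("non-finite entries in predictors or outcome")
    if y.shape[0] < cv_folds:
        raise ValueError(f"n={y.shape[0]} below the number of CV folds ({cv_folds})")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    if design is not None:
        y = residualize(y, design)
        X = np.column_stack([residualize(X[:, j], design) for j in range(X.shape[1])])
        X = _standardize(X)
        y = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=alpha,
        alphas=n_lambda,  # size of the automatic log-spaced grid
        eps=1e-4,
        cv=cv,
        tol=1e-7,
        max_iter=50_000,
        fit_intercept=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(X, y)

    grid = enet.alphas_
    if lambda_rule == "min":
        lam = float(enet.alpha_)
        beta = enet.coef_.copy()
    else:
        mse = enet.mse_path_.mean(axis=1)
        se = enet.mse_path_.std(axis=1, ddof=1) / np.sqrt(enet.mse_path_.shape[1])
        i_min = int(np.argmin(mse))
        cutoff = mse[i_min] + se[i_min]
        # grid is descending; the largest admissible lambda is the first
        i_1se = int(np.argmax(mse <= cutoff))
        lam = float(grid[i_1se])
        refit = ElasticNet(alpha=lam, l1_ratio=alpha, tol=1e-7, max_iter=50_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit.fit(X, y)
        beta = refit.coef_.copy()

    selected = np.flatnonzero(beta != 0.0)
    return ElasticNetModel(
        alpha=alpha,
        lambda_grid=grid,
        lambda_selected=lam,
        beta=beta,
        selected=selected,
        cv_folds=cv_folds,
        seed=seed,
        lambda_rule=lambda_rule,
    )


def cross_sample_predict(
    selected: np.ndarray,
    source: str,
    target: str,
    target_g: np.ndarray,
    target_X: np.ndarray,
    design: CovariateDesign,
    bonferroni_m: int = 16,
    mode: str = "residualized",
) -> PredictionResult:
    """Validate a predictor set in another sample by multiple regression.

    Regresses g on the selected nodal metrics in the target cohort and
    reports R^2, the overall F-test p, and Bonferroni significance at
    0.05/``bonferroni_m``.  ``mode='residualized'`` removes the control
    design from g and the predictors first; ``mode='covariates_in_model'``
    instead includes the controls as additional regressors (R^2 then
    measured against the controls-only model is not reported).  An empty
    predictor set yields a flagged placeholder row.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        return PredictionResult(
            source=source,
            target=target,
            n_predictors=0,
            r_squared=None,
            p_raw=None,
            significant_bonferroni=False,
            note="no predictors",
        )
    y = np.asarray(target_g, dtype=float)
    X = np.asarray(target_X, dtype=float)[:, selected]
    if mode == "residualized":
        y = residualize(y, design)
        X = np.column_stack([residualize(X[:, j], design) for j in range(X.shape[1])])
        model = sm.OLS(y, sm.add_constant(X)).fit()
    elif mode == "covariates_in_model":
        model = sm.OLS(y, np.column_stack([sm.add_constant(X), design.matrix])).fit()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = float(model.f_pvalue)
    return PredictionResult(
        source=source,
        target=target,
        n_predictors=int(selected.size),
        r_squared=float(model.rsquared),
        p_raw=p,
        significant_bonferroni=bool(p < bonferroni_threshold(0.05, bonferroni_m)),
    )


def predictor_overlap(
    supports: dict[str, set[int]],
    effects: dict[str, dict[int, float]] | None = None,
) -> dict:
    """Overlap report for predictor sets selected in different samples.

    Returns pairwise and all-way intersections, the overlap percentage
    of the all-way intersection relative to the union, and per-area
    effect sizes averaged over the samples that selected the area.
    """
    if len(supports) < 2:
        raise ValueError("need at least two predictor sets")
    names = list(supports)
    sets = {k: set(v) for k, v in supports.items()}
    pairwise = {
        f"{a}&{b}": sorted(sets[a] & sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    allway = set.intersection(*sets.values())
    union = set.union(*sets.values())
    pct = 100.0 if not union else 100.0 * len(allway) / len(union)
    avg_effects: dict[int, float] = {}
    if effects is not None:
        for area in sorted(union):
            vals = [effects[k][area] for k in names if area in sets[k] and area in effects.get(k, {})]
            if vals:
                avg_effects[area] = float(np.mean(vals))
    return {
        "pairwise": pairwise,
        "all_way": sorted(allway),
        "union": sorted(union),
        "overlap_pct": pct,
        "averaged_effects": avg_effects,
    }


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------


def icc_3_1(measurements: np.ndarray) -> float:
    """ICC(3,1): two-way mixed-effects, single-measure, consistency.

    From the subjects x sessions ANOVA decomposition:
    ICC = (BMS - EMS) / (BMS + (k - 1) * EMS), with BMS the
    between-subject and EMS the residual mean square.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a subjects x sessions matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 sessions")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing or non-finite cells are not supported")
    grand = m.mean()
    subj = m.mean(axis=1)
    sess = m.mean(axis=0)
    ss_subj = k * np.sum((subj - grand) ** 2)
    ss_sess = n * np.sum((sess - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_resid = ss_total - ss_subj - ss_sess
    bms = ss_subj / (n - 1)
    ems = ss_resid / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    if denom == 0:
        return 0.0
    return float((bms - ems) / denom)


def spearman_brown(r: float) -> float:
    """Split-half correction SB = 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    bundles: list[TimeSeriesBundle],
    max_trees: int = 50,
    clip_before_z: bool = True,
) -> pd.DataFrame:
    """Odd/even split-half reliability of global graph metrics.

    Each subject's time series is split into odd- and even-indexed
    volumes; each half runs through the full chain (connectivity -> OMST
    -> metrics).  Across subjects, the Pearson correlation between
    half-derived metrics is corrected with Spearman-Brown.
    """
    if len(bundles) < 3:
        raise ValueError("split-half reliability needs at least 3 subjects")
    if any(b.n_volumes < 20 for b in bundles):
        raise ValueError("need at least 20 volumes per subject for a stable split")

    halves: dict[str, list[list[float]]] = {"odd": [], "even": []}
    for b in bundles:
        for name, sl in (("odd", slice(0, None, 2)), ("even", slice(1, None, 2))):
            half = TimeSeriesBundle(
                node_series=b.node_series[:, sl],
                confound_series=b.confound_series[:, sl] if b.n_confounds else np.empty((0, b.node_series[:, sl].shape[1])),
                tr_seconds=b.tr_seconds,
                subject_id=b.subject_id,
                session_id=f"{b.session_id}-{name}",
            )
            conn = build_connectivity(half, clip_before_z=clip_before_z)
            pruned = omst_filter(conn, max_trees=max_trees)
            e, _ = efficiency(pruned.network)
            c, _ = clustering(pruned.network)
            halves[name].append([e, c])

    odd = np.asarray(halves["odd"])
    even = np.asarray(halves["even"])
    rows = []
    for j, metric in enumerate(["global_efficiency", "global_clustering"]):
        r = float(np.corrcoef(odd[:, j], even[:, j])[0, 1])
        rows.append({"metric": metric, "kind": "split_half_sb", "r": r, "sb": spearman_brown(r)})
    return pd.DataFrame(rows)


def lateralization_quotient(right: int, left: int) -> tuple[float, int]:
    """Edinburgh-inventory LQ = (R - L)/(R + L) * 100; code 1 iff LQ >= 60."""
    if right + left <= 0:
        raise ValueError("R + L must be positive")
    lq = (right - left) / (right + left) * 100.0
    return float(lq), int(lq >= 60.0)
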