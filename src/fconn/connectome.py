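"""Construction of functional connectivity matrices from node time series.

Pipeline order is fixed: pairwise partial correlations controlling the
confound series -> negative clipping -> Fisher z.  "Partial correlation"
here means the Pearson correlation of the two node series after each has
been residualized on the confound series plus an intercept; other nodes
are not partialed out (full-precision partialing over hundreds of nodes
would require more volumes than nodes, which resting-state scans rarely
provide).
"""

from __future__ import annotations

import numpy as np

from .containers import ConnectivityMatrix, TimeSeriesBundle

__all__ = [
    "partial_correlation_matrix",
    "clip_negatives",
    "fisher_z",
    "concatenate_sessions",
    "build_connectivity",
    "PERFECT_R_CAP",
]

#: correlations of exactly 1 are capped here before artanh so edge
#: weights stay finite for the downstream spanning-tree filter
PERFECT_R_CAP = 1.0 - 1e-7


def _residualize_on_confounds(ts: TimeSeriesBundle) -> np.ndarray:
    x = ts.node_series
    t = ts.n_volumes
    design = np.column_stack([np.ones(t)] + [c for c in ts.confound_series])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ beta).T


def partial_correlation_matrix(ts: TimeSeriesBundle) -> ConnectivityMatrix:
    """Pairwise partial correlations of node series, controlling confounds.

    Returns a symmetric ``raw_r`` matrix with zero diagonal.  Errors if
    the series are too short (T must exceed n_confounds + 2) or if any
    node has zero variance before or after confound removal.
    """
    if ts.n_volumes <= ts.n_confounds + 2:
        raise ValueError(
            f"need T > n_confounds + 2 for partial correlations "
            f"(T={ts.n_volumes}, confounds={ts.n_confounds})"
        )
    sd_raw = ts.node_series.std(axis=1)
    if np.any(sd_raw == 0):
        bad = int(np.argmax(sd_raw == 0))
        raise ValueError(f"node {bad} has a constant time series")
    resid = _residualize_on_confounds(ts)
    sd = resid.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"node {bad} has zero variance after confound removal")
    corr = np.corrcoef(resid)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return ConnectivityMatrix((corr + corr.T) / 2.0, stage="raw_r")


def clip_negatives(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Replace negative correlations with zeros (stage raw_r -> clipped)."""
    if matrix.stage != "raw_r":
        raise ValueError(f"expected stage 'raw_r', got {matrix.stage!r}")
    return ConnectivityMatrix(np.maximum(matrix.values, 0.0), stage="clipped", labels=matrix.labels)


def fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z-transform (artanh) of clipped correlations.

    Entries equal to 1 are first capped at ``PERFECT_R_CAP`` so the
    transform stays finite; entries above 1 are a data error.
    """
    if matrix.stage != "clipped":
        raise ValueError(f"expected stage 'clipped', got {matrix.stage!r}")
    v = matrix.values
    if np.any(v > 1.0):
        raise ValueError("correlation entries above 1 are not valid")
    v = np.minimum(v, PERFECT_R_CAP)
    return ConnectivityMatrix(np.arctanh(v), stage="fisher_z", labels=matrix.labels)


def concatenate_sessions(
    bundles: list[TimeSeriesBundle],
    standardize: bool = True,
) -> TimeSeriesBundle:
    """Join sessions along time, z-standardizing each series per session.

    Per-session standardization removes inter-session scale and offset
    differences so the concatenated correlation reflects the shared
    covariance structure.  Set ``standardize=False`` for raw
    concatenation.
    """
    if not bundles:
        raise ValueError("no bundles to concatenate")
    n_nodes = bundles[0].n_nodes
    n_conf = bundles[0].n_confounds
    for b in bundles[1:]:
        if b.n_nodes != n_nodes:
            raise ValueError(f"node count mismatch: {b.n_nodes} != {n_nodes}")
        if b.n_confounds != n_conf:
            raise ValueError(f"confound count mismatch: {b.n_confounds} != {n_conf}")

    def _z(x: np.ndarray) -> np.ndarray:
        if not standardize or x.size == 0:
            return x
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (x - x.mean(axis=1, keepdims=True)) / sd

    nodes = np.hstack([_z(b.node_series) for b in bundles])
    confs = np.hstack([_z(b.confound_series) for b in bundles])
    return TimeSeriesBundle(
        node_series=nodes,
        confound_series=confs,
        tr_seconds=bundles[0].tr_seconds,
        subject_id=bundles[0].subject_id,
        session_id="+".join(b.session_id for b in bundles),
    )


def build_connectivity(
    ts: TimeSeriesBundle,
    clip_before_z: bool = True,
) -> ConnectivityMatrix:
    """Full connectivity construction: partial correlation, clip, Fisher z.

    ``clip_before_z=True`` is the default pipeline order (clip, then
    artanh of the already-clipped values); the alternative order applies
    artanh first and then zeroes negatives, and is exposed because the
    original convention is ambiguous.  Both yield identical results on
    nonnegative entries since artanh(0) = 0 and artanh is increasing.
    """
    raw = partial_correlation_matrix(ts)
    if clip_before_z:
        return fisher_z(clip_negatives(raw))
    v = np.clip(raw.values, -PERFECT_R_CAP, PERFECT_R_CAP)
    z = np.arctanh(v)
    return ConnectivityMatrix(np.maximum(z, 0.0), stage="fisher_z", labels=raw.labels)
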