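"""Shared in-memory containers for weighted networks and BOLD-like series.

All heavy data live in plain numpy arrays; these classes only add the
invariants the analysis relies on (symmetry, zero diagonal, matching
time axes) and fail loudly when they are violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["WeightedNetwork", "ConnectivityMatrix", "TimeSeriesBundle", "STAGES"]

#: Processing stages of a connectivity matrix, in pipeline order.
STAGES = ("raw_r", "clipped", "fisher_z")

_SYM_TOL = 1e-12


def _check_square_symmetric(values: np.ndarray, tol: float = _SYM_TOL) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got shape {values.shape}")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > tol:
        raise ValueError(f"matrix asymmetry {asym:.3e} exceeds tolerance {tol:.0e}")
    return values


@dataclass
class WeightedNetwork:
    """Symmetric, nonnegative, zero-diagonal edge-weighted graph.

    ``weights[i, j]`` is the weight of the undirected edge (i, j); a zero
    entry means the edge is absent.
    """

    weights: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = _check_square_symmetric(self.weights)
        if np.any(~np.isfinite(w)):
            raise ValueError("network weights must be finite")
        if np.any(w < 0):
            raise ValueError("network weights must be nonnegative")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        # exact symmetry after the tolerance check
        self.weights = (w + w.T) / 2.0
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("label count does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_possible_edges(self) -> int:
        """Unique node pairs: one triangle of the adjacency matrix."""
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def n_edges(self) -> int:
        """Number of present (positive-weight) edges."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu] > 0))

    @property
    def total_weight(self) -> float:
        """Sum of edge weights over unique pairs."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return float(self.weights[iu].sum())

    def is_connected(self) -> bool:
        adj = csr_matrix(self.weights > 0)
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1

    def node_labels(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        return [f"node{i:03d}" for i in range(self.n_nodes)]


@dataclass
class ConnectivityMatrix:
    """Functional connectivity matrix with an explicit processing stage.

    Stages follow the fixed pipeline order ``raw_r`` (pairwise partial
    correlations) -> ``clipped`` (negatives zeroed) -> ``fisher_z``
    (artanh-transformed).  Post-clip stages must be nonnegative.
    """

    values: np.ndarray
    stage: str = "raw_r"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        v = _check_square_symmetric(self.values)
        if np.any(~np.isfinite(v)):
            raise ValueError("connectivity values must be finite")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        self.values = (v + v.T) / 2.0
        if self.stage in ("clipped", "fisher_z") and np.any(self.values < 0):
            raise ValueError(f"stage {self.stage!r} requires nonnegative entries")
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("label count does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_network(self) -> WeightedNetwork:
        if self.stage == "raw_r":
            raise ValueError("raw correlation matrices may be negative; clip first")
        return WeightedNetwork(self.values.copy(), labels=self.labels)


@dataclass
class TimeSeriesBundle:
    """Per-subject node time series plus nuisance confound series.

    ``node_series`` is nodes x volumes; ``confound_series`` is
    confounds x volumes (possibly 0 confounds) on the same time axis.
    """

    node_series: np.ndarray
    confound_series: np.ndarray
    tr_seconds: float
    subject_id: str = "sub-00"
    session_id: str = "ses-01"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_series = np.atleast_2d(np.asarray(self.node_series, dtype=float))
        self.confound_series = np.asarray(self.confound_series, dtype=float)
        if self.confound_series.size == 0:
            self.confound_series = np.empty((0, self.node_series.shape[1]))
        self.confound_series = np.atleast_2d(self.confound_series)
        if self.node_series.shape[1] != self.confound_series.shape[1]:
            raise ValueError(
                "node and confound series must share the time axis: "
                f"{self.node_series.shape[1]} != {self.confound_series.shape[1]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_nodes(self) -> int:
        return self.node_series.shape[0]

    @property
    def n_confounds(self) -> int:
        return self.confound_series.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.node_series.shape[1]
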