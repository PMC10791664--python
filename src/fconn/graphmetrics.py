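"""Weighted graph metrics for pruned functional connectomes.

Implements the five measures of the analysis: global efficiency, nodal
efficiency, global clustering, local clustering, and small-world
propensity.  All path-based quantities use the inverse-weight distance
convention d_ij = 1 / w_ij, so strong functional connections are short.

Efficiency
    E_i = (1 / (n - 1)) * sum_{j != i} 1 / d_ij,   E = mean_i E_i

Clustering (geometric-mean triangle intensity on max-normalized weights)
    C_i = 2 t_i / (k_i (k_i - 1)),
    t_i = (1/2) * sum_{j,h} (w_ij w_ih w_jh)^(1/3)

Small-world propensity
    phi = 1 - sqrt((dC^2 + dL^2) / 2)
with dC, dL locating the observed clustering and characteristic path
length between matched lattice and random null networks, clamped to
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .containers import WeightedNetwork

__all__ = [
    "DisconnectedGraphError",
    "SWPResult",
    "GraphMetricSet",
    "shortest_path_lengths",
    "efficiency",
    "clustering",
    "characteristic_path_length",
    "small_world_propensity",
    "lattice_null",
    "random_null",
    "compute_metrics",
]


class DisconnectedGraphError(ValueError):
    """The graph is not connected and the requested metric is undefined."""


def _as_weights(network: WeightedNetwork | np.ndarray) -> np.ndarray:
    if isinstance(network, WeightedNetwork):
        return network.weights
    return WeightedNetwork(np.asarray(network, dtype=float)).weights


def shortest_path_lengths(network: WeightedNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on 1/w distances (Dijkstra).

    Raises :class:`DisconnectedGraphError` if any pair is unreachable.
    """
    w = _as_weights(network)
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = _csgraph_shortest_path(csr_matrix(dist), method="D", directed=False)
    if not np.all(np.isfinite(d)):
        raise DisconnectedGraphError(
            "graph is disconnected; shortest path lengths are infinite for some pairs"
        )
    np.fill_diagonal(d, 0.0)
    return d


def efficiency(network: WeightedNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """Global and nodal efficiency: average inverse shortest path length."""
    w = _as_weights(network)
    n = w.shape[0]
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    d = shortest_path_lengths(w)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    inv[off] = 1.0 / d[off]
    e_i = inv.sum(axis=1) / (n - 1)
    return float(e_i.mean()), e_i


def clustering(network: WeightedNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """Global and local weighted clustering coefficients.

    Weights are first rescaled by the global maximum so every edge lies
    in [0, 1]; triangle intensity uses the geometric mean of the three
    edge weights; nodes with fewer than two neighbors get C_i = 0.
    """
    w = _as_weights(network).copy()
    n = w.shape[0]
    wmax = w.max()
    if wmax > 0:
        w = w / wmax
    a = np.cbrt(w)
    t = np.diag(a @ a @ a) / 2.0
    k = np.count_nonzero(w > 0, axis=1).astype(float)
    c_i = np.zeros(n)
    mask = k >= 2
    c_i[mask] = 2.0 * t[mask] / (k[mask] * (k[mask] - 1.0))
    return float(c_i.mean()), c_i


def characteristic_path_length(network: WeightedNetwork | np.ndarray) -> float:
    """Mean shortest path length over all ordered pairs i != j."""
    w = _as_weights(network)
    n = w.shape[0]
    d = shortest_path_lengths(w)
    off = ~np.eye(n, dtype=bool)
    return float(d[off].mean())


# ---------------------------------------------------------------------------
# small-world propensity with lattice / random nulls
# ---------------------------------------------------------------------------


def _ring_ordered_pairs(n: int) -> list[tuple[int, int]]:
    """All node pairs ordered by increasing ring distance, then node index."""
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for r in range(1, n // 2 + 1):
        for i in range(n):
            j = (i + r) % n
            e = (min(i, j), max(i, j))
            if e not in seen:
                seen.add(e)
                pairs.append(e)
    return pairs


def lattice_null(network: WeightedNetwork | np.ndarray) -> WeightedNetwork:
    """Ring-lattice null: same nodes and edge count; observed weights
    sorted descending and placed on edges of increasing ring distance."""
    w = _as_weights(network)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = w[iu]
    weights = np.sort(weights[weights > 0])[::-1]
    out = np.zeros_like(w)
    for wt, (i, j) in zip(weights, _ring_ordered_pairs(n)):
        out[i, j] = out[j, i] = wt
    return WeightedNetwork(out)


def random_null(
    network: WeightedNetwork | np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> WeightedNetwork:
    """Random null: same node and edge count, edges placed uniformly at
    random with the observed weights randomly assigned; disconnected
    draws are rejected and redrawn (up to ``max_attempts``)."""
    w = _as_weights(network)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = w[iu]
    weights = weights[weights > 0]
    m = weights.size
    n_pairs = n * (n - 1) // 2
    for _ in range(max_attempts):
        idx = rng.choice(n_pairs, size=m, replace=False)
        vals = rng.permutation(weights)
        out = np.zeros_like(w)
        out[iu[0][idx], iu[1][idx]] = vals
        out = out + out.T
        net = WeightedNetwork(out)
        if net.is_connected():
            return net
    raise RuntimeError(
        f"no connected random null found in {max_attempts} attempts; "
        "the graph may be too sparse for this null model"
    )


@dataclass
class SWPResult:
    phi: float
    delta_c: float
    delta_l: float
    c_obs: float
    c_latt: float
    c_rand: float
    l_obs: float
    l_latt: float
    l_rand: float
    n_null: int
    seed: int


def _safe_delta(numer: float, denom: float) -> float:
    if denom == 0.0:
        val = 0.0 if numer <= 0 else 1.0
    else:
        val = numer / denom
    return float(np.clip(val, 0.0, 1.0))


def small_world_propensity(
    network: WeightedNetwork | np.ndarray,
    n_null: int = 10,
    seed: int = 0,
) -> SWPResult:
    """Small-world propensity phi with lattice and random null networks.

    dC = (C_latt - C_obs) / (C_latt - C_rand)
    dL = (L_obs - L_rand) / (L_latt - L_rand)
    phi = 1 - sqrt((dC^2 + dL^2) / 2)

    dC and dL are clamped to [0, 1]; random-null statistics are averaged
    over ``n_null`` connected realizations.
    """
    w = _as_weights(network)
    n = w.shape[0]
    if n < 4:
        raise ValueError("small-world propensity requires at least 4 nodes")
    net = WeightedNetwork(w)
    if not net.is_connected():
        raise DisconnectedGraphError("small-world propensity requires a connected graph")

    c_obs, _ = clustering(w)
    l_obs = characteristic_path_length(w)

    latt = lattice_null(w)
    c_latt, _ = clustering(latt.weights)
    # a sparse lattice may be disconnected; path length then undefined ->
    # fall back to the observed value (dL contribution clamps to [0, 1])
    try:
        l_latt = characteristic_path_length(latt.weights)
    except DisconnectedGraphError:
        l_latt = l_obs

    rng = np.random.default_rng(seed)
    c_rands, l_rands = [], []
    for _ in range(n_null):
        rand = random_null(w, rng)
        c_rands.append(clustering(rand.weights)[0])
        l_rands.append(characteristic_path_length(rand.weights))
    c_rand = float(np.mean(c_rands))
    l_rand = float(np.mean(l_rands))

    delta_c = _safe_delta(c_latt - c_obs, c_latt - c_rand)
    delta_l = _safe_delta(l_obs - l_rand, l_latt - l_rand)
    phi = 1.0 - np.sqrt((delta_c**2 + delta_l**2) / 2.0)
    return SWPResult(
        phi=float(np.clip(phi, 0.0, 1.0)),
        delta_c=delta_c,
        delta_l=delta_l,
        c_obs=c_obs,
        c_latt=c_latt,
        c_rand=c_rand,
        l_obs=l_obs,
        l_latt=l_latt,
        l_rand=l_rand,
        n_null=n_null,
        seed=seed,
    )


@dataclass
class GraphMetricSet:
    """Bundle of per-network metrics: E, E_i, C, C_i, L_obs, optional SWP."""

    global_efficiency: float
    nodal_efficiency: np.ndarray
    global_clustering: float
    local_clustering: np.ndarray
    char_path_length: float
    swp: SWPResult | None = None
    extras: dict = field(default_factory=dict)


def compute_metrics(
    network: WeightedNetwork | np.ndarray,
    swp: bool = False,
    n_null: int = 10,
    seed: int = 0,
) -> GraphMetricSet:
    """Compute the full metric set on one (pruned) weighted network."""
    w = _as_weights(network)
    e, e_i = efficiency(w)
    c, c_i = clustering(w)
    l_obs = characteristic_path_length(w)
    swp_res = small_world_propensity(w, n_null=n_null, seed=seed) if swp else None
    return GraphMetricSet(
        global_efficiency=e,
        nodal_efficiency=e_i,
        global_clustering=c,
        local_clustering=c_i,
        char_path_length=l_obs,
        swp=swp_res,
    )
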