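"""Orthogonal-minimum-spanning-tree (OMST) topological filtering.

Dense functional connectomes contain many weak, probably spurious edges.
Instead of an arbitrary density or weight threshold, OMST extracts
successive minimum spanning trees on inverse-weight distances (so each
tree keeps the strongest available backbone), zeroing out each tree's
edges before extracting the next so the trees are pairwise
edge-disjoint.  The union of the first m trees is scored by

    GCE(m) = E(U_m) / E(G) - cost(m)

where E is global efficiency, E(G) the efficiency of the unfiltered
graph, and cost(m) the ratio of selected to total edge weight.  The
returned network is the union at the global argmax of the GCE curve; it
is connected by construction (it contains the first tree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ConnectivityMatrix, WeightedNetwork
from .graphmetrics import efficiency

__all__ = ["NoSpanningTree", "PrunedGraph", "kruskal_mst", "global_cost_efficiency", "omst_filter"]

Edge = tuple[int, int]


class NoSpanningTree(Exception):
    """The positive-weight subgraph (after exclusions) is disconnected."""


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def _as_weights(network: WeightedNetwork | ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(network, WeightedNetwork):
        return network.weights
    if isinstance(network, ConnectivityMatrix):
        if np.any(network.values < 0):
            raise ValueError("OMST operates on nonnegative (clipped) weights")
        return network.values
    return WeightedNetwork(np.asarray(network, dtype=float)).weights


def kruskal_mst(
    network: WeightedNetwork | ConnectivityMatrix | np.ndarray,
    excluded_edges: set[Edge] | frozenset[Edge] = frozenset(),
) -> list[Edge]:
    """Minimum spanning tree on distances d = 1/w via Kruskal's algorithm.

    Edges are sorted by (distance, smaller node index, larger node index)
    so the result is deterministic under weight ties.  Excluded edges and
    zero-weight pairs are unavailable.  Raises :class:`NoSpanningTree` if
    the remaining graph is disconnected.
    """
    w = _as_weights(network)
    n = w.shape[0]
    excluded = {(min(i, j), max(i, j)) for i, j in excluded_edges}
    iu, ju = np.triu_indices(n, k=1)
    keep = w[iu, ju] > 0
    cand = [
        (1.0 / w[i, j], i, j)
        for i, j in zip(iu[keep], ju[keep])
        if (i, j) not in excluded
    ]
    cand.sort()
    uf = _UnionFind(n)
    tree: list[Edge] = []
    for _, i, j in cand:
        if uf.union(int(i), int(j)):
            tree.append((int(i), int(j)))
            if len(tree) == n - 1:
                return tree
    raise NoSpanningTree(
        f"only {len(tree)} of {n - 1} tree edges found; remaining graph is disconnected"
    )


def global_cost_efficiency(
    selected: WeightedNetwork | np.ndarray,
    original: WeightedNetwork | np.ndarray,
) -> float:
    """GCE = E(selected)/E(original) - sum(selected w)/sum(original w).

    The efficiency term is normalized by the unfiltered graph's global
    efficiency so that it is scale-free and comparable with the wiring
    cost; selecting the full graph therefore gives GCE = 0.
    """
    sel = selected if isinstance(selected, WeightedNetwork) else WeightedNetwork(np.asarray(selected, dtype=float))
    orig = original if isinstance(original, WeightedNetwork) else WeightedNetwork(np.asarray(original, dtype=float))
    if orig.total_weight <= 0:
        raise ValueError("original graph has no positive edges")
    if np.any(sel.weights[orig.weights == 0] > 0):
        raise ValueError("selected edges must be a subset of the original edges")
    e_sel, _ = efficiency(sel)
    e_orig, _ = efficiency(orig)
    cost = sel.total_weight / orig.total_weight
    return float(e_sel / e_orig - cost)


@dataclass
class PrunedGraph:
    """OMST-filtered network plus the diagnostics of the optimization."""

    network: WeightedNetwork
    n_trees: int
    wiring_cost: float
    gce: float
    gce_curve: list[tuple[int, float]]


def omst_filter(
    matrix: ConnectivityMatrix | WeightedNetwork | np.ndarray,
    max_trees: int = 50,
) -> PrunedGraph:
    """Topologically filter a connectivity matrix by orthogonal MSTs.

    Extracts edge-disjoint MSTs round by round, evaluating the global
    cost efficiency of the aggregated union after every round, until no
    spanning tree remains or ``max_trees`` rounds have run; returns the
    union with maximal GCE (first maximum on exact ties).
    """
    if isinstance(matrix, ConnectivityMatrix) and matrix.stage == "raw_r":
        raise ValueError("filter after clipping negatives (stage raw_r given)")
    w = _as_weights(matrix)
    labels = getattr(matrix, "labels", None)
    n = w.shape[0]
    full = WeightedNetwork(w, labels=labels)
    if not full.is_connected():
        raise ValueError(
            "input connectivity matrix is disconnected; OMST requires a connected "
            "positive-weight graph"
        )

    e_orig, _ = efficiency(full)
    total_w = full.total_weight
    excluded: set[Edge] = set()
    trees: list[list[Edge]] = []
    union = np.zeros_like(w)
    gce_curve: list[tuple[int, float]] = []
    costs: list[float] = []

    for m in range(1, max_trees + 1):
        try:
            tree = kruskal_mst(full, excluded)
        except NoSpanningTree:
            break
        # orthogonality: a selected edge can never reappear
        assert not (set(tree) & excluded), "MST rounds must be edge-disjoint"
        excluded |= set(tree)
        trees.append(tree)
        for i, j in tree:
            union[i, j] = union[j, i] = w[i, j]
        sel = WeightedNetwork(union)
        e_sel, _ = efficiency(sel)
        cost = sel.total_weight / total_w
        costs.append(cost)
        gce_curve.append((m, float(e_sel / e_orig - cost)))

    if not gce_curve:
        raise ValueError("no spanning tree could be extracted")

    gces = [g for _, g in gce_curve]
    m_star = int(np.argmax(gces)) + 1

    best = np.zeros_like(w)
    for tree in trees[:m_star]:
        for i, j in tree:
            best[i, j] = best[j, i] = w[i, j]
    network = WeightedNetwork(best, labels=labels)
    assert network.is_connected(), "pruned network must be connected"
    return PrunedGraph(
        network=network,
        n_trees=m_star,
        wiring_cost=costs[m_star - 1],
        gce=gces[m_star - 1],
        gce_curve=gce_curve,
    )
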