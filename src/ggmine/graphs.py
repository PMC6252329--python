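"""Proximity graphs on embedded trials, hub detection and global efficiency.

Four planar proximity graphs are supported — the Euclidean minimum spanning
tree (EMST), relative neighborhood graph (RNG), Gabriel graph (GG) and
Delaunay triangulation (DT) — which nest as EMST ⊆ RNG ⊆ GG ⊆ DT.  The
Gabriel graph connects p and q iff no third point lies strictly inside the
closed disk with diameter pq, equivalently iff d(p,q)² < d(p,k)² + d(q,k)²
for every other point k.  GG and RNG are computed by filtering Delaunay
candidate edges (every GG/RNG edge is a DT edge), which replaces the naive
O(n³) scan by O(|DT| · n).

Representative trials ("hubs") are the GG nodes whose degree reaches a
threshold k; the spread of the selected hubs is summarized by the weighted
global efficiency of their mutual-distance graph.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

from .embedding import PointSet2D

__all__ = [
    "ProximityGraph",
    "HubSelection",
    "gabriel_graph",
    "rng_graph",
    "emst",
    "delaunay",
    "select_hubs",
    "global_efficiency",
    "hub_variability_ge",
    "EmptySelectionError",
]

# Boundary ties (a point exactly on the diametral circle / lune boundary) do
# not block an edge: the predicate is strict, with this relative tolerance on
# squared distances to keep right angles stable under floating-point noise.
_RTOL = 1e-9


class EmptySelectionError(ValueError):
    pass


@dataclass(frozen=True)
class ProximityGraph:
    """Undirected graph over (possibly collapsed) embedded points.

    ``rep_of`` maps each original point index to its node: exact duplicate
    points are collapsed to a single node before construction, since the
    geometric predicates are undefined on coincident points.
    """

    n_nodes: int
    edges: frozenset
    kind: str
    rep_of: np.ndarray
    lengths: Optional[dict] = field(default=None)

    @property
    def n_points(self) -> int:
        return self.rep_of.size

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def edge_array(self) -> np.ndarray:
        return np.array(sorted(self.edges), dtype=int).reshape(-1, 2)


@dataclass(frozen=True)
class HubSelection:
    """Trials whose Gabriel-graph degree reaches the threshold k."""

    k: int
    selected: np.ndarray
    degree_table: np.ndarray  # per original point

    @property
    def n_selected(self) -> int:
        return self.selected.size


def _collapse(points: PointSet2D) -> tuple[np.ndarray, np.ndarray]:
    """Unique points in first-occurrence order plus the point -> node map."""
    coords = points.coords
    _, first, inv = np.unique(
        coords, axis=0, return_index=True, return_inverse=True
    )
    if first.size < coords.shape[0]:
        warnings.warn(
            f"collapsed {coords.shape[0] - first.size} duplicate point(s) "
            "before graph construction"
        )
    order = np.argsort(first)  # nodes keep the original point order
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return coords[np.sort(first)], rank[inv.ravel()]


def _delaunay_edges(coords: np.ndarray) -> Optional[set]:
    """Delaunay edge set, or None when the point set is degenerate."""
    if coords.shape[0] < 3:
        return None
    try:
        tri = Delaunay(coords)
    except QhullError:
        return None
    edges = set()
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex, 2):
            edges.add((int(min(a, b)), int(max(a, b))))
    return edges


def _path_fallback(coords: np.ndarray) -> set:
    """Path graph along the principal axis for all-collinear point sets."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(centered @ vt[0])
    return {
        (int(min(a, b)), int(max(a, b))) for a, b in zip(order[:-1], order[1:])
    }


def _filter_candidates(coords: np.ndarray, candidates, predicate) -> frozenset:
    d2 = squareform(pdist(coords)) ** 2
    n = coords.shape[0]
    kept = set()
    for p, q in candidates:
        k_mask = np.ones(n, dtype=bool)
        k_mask[[p, q]] = False
        if not predicate(d2, p, q, k_mask):
            kept.add((int(p), int(q)))
    return frozenset(kept)


def _gg_blocked(d2, p, q, k_mask) -> bool:
    return bool(
        np.any(d2[p, k_mask] + d2[q, k_mask] < d2[p, q] * (1.0 - _RTOL))
    )


def _rng_blocked(d2, p, q, k_mask) -> bool:
    return bool(
        np.any(
            np.maximum(d2[p, k_mask], d2[q, k_mask]) < d2[p, q] * (1.0 - _RTOL)
        )
    )


def _proximity(points: PointSet2D, predicate, kind: str) -> ProximityGraph:
    coords, rep_of = _collapse(points)
    n = coords.shape[0]
    if n < 2:
        if kind in ("gg", "rng") and n == 1:
            # all points coincide: a single representative node, no edges
            return ProximityGraph(1, frozenset(), kind, rep_of)
        raise ValueError("need at least 2 distinct points")
    candidates = _delaunay_edges(coords)
    if candidates is None:
        candidates = set(itertools.combinations(range(n), 2))
    edges = _filter_candidates(coords, candidates, predicate)
    return ProximityGraph(n, edges, kind, rep_of)


def gabriel_graph(points: PointSet2D) -> ProximityGraph:
    """Gabriel graph: edge (p,q) iff the diametral disk of pq is empty."""
    return _proximity(points, _gg_blocked, "gg")


def rng_graph(points: PointSet2D) -> ProximityGraph:
    """Relative neighborhood graph: edge (p,q) iff the lune of pq is empty."""
    return _proximity(points, _rng_blocked, "rng")


def emst(points: PointSet2D) -> ProximityGraph:
    """Euclidean minimum spanning tree (minimal total edge length)."""
    coords, rep_of = _collapse(points)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 distinct points")
    dist = squareform(pdist(coords))
    mst = minimum_spanning_tree(csr_matrix(dist)).tocoo()
    edges, lengths = set(), {}
    for a, b, w in zip(mst.row, mst.col, mst.data):
        e = (min(int(a), int(b)), max(int(a), int(b)))
        edges.add(e)
        lengths[e] = float(w)
    return ProximityGraph(n, frozenset(edges), "emst", rep_of, lengths)


def delaunay(points: PointSet2D) -> ProximityGraph:
    """Delaunay triangulation edge set (path-graph fallback when collinear)."""
    coords, rep_of = _collapse(points)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 distinct points")
    edges = _delaunay_edges(coords)
    if edges is None:
        warnings.warn("degenerate (collinear or tiny) point set: path-graph fallback")
        edges = {(0, 1)} if n == 2 else _path_fallback(coords)
    return ProximityGraph(n, frozenset(edges), "dt", rep_of)


def select_hubs(g: ProximityGraph, k: int) -> HubSelection:
    """Original point indices whose node degree is >= k.

    Duplicate points inherit their representative node's hub status.  The
    degenerate single-node graph (all points coincident) selects everything.
    """
    if k < 1:
        raise ValueError("degree threshold k must be >= 1")
    if g.n_nodes == 1:
        deg_per_point = np.zeros(g.n_points, dtype=int)
        return HubSelection(k, np.arange(g.n_points), deg_per_point)
    deg_per_point = g.degrees[g.rep_of]
    selected = np.flatnonzero(deg_per_point >= k)
    if selected.size == 0:
        raise EmptySelectionError(
            f"no node has degree >= {k}; retry with k = {k - 1}"
        )
    return HubSelection(k, selected, deg_per_point)


def _ge_from_lengths(n: int, edges_lengths: dict) -> float:
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    rows, cols, data = [], [], []
    for (i, j), w in edges_lengths.items():
        if not np.isfinite(w) or w <= 0:
            continue
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    mat = csr_matrix((data, (rows, cols)), shape=(n, n))
    d = dijkstra(mat, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: ProximityGraph) -> float:
    """GE = mean over ordered node pairs of 1 / shortest-path length.

    Edge lengths default to 1 when the graph carries none; disconnected
    pairs contribute 0 (the 1/∞ convention).  Lies in [0, 1] whenever all
    finite edge lengths are >= 1.
    """
    lengths = g.lengths or {e: 1.0 for e in g.edges}
    return _ge_from_lengths(g.n_nodes, lengths)


def hub_variability_ge(points: PointSet2D, hubs: HubSelection) -> float:
    """Variability of the selected hubs as weighted global efficiency.

    Pairwise Euclidean distances among hub coordinates are normalized by
    their maximum (ŵ = d / d_max) and inverted into functional weights
    w = 1 - ŵ, so closer hubs communicate more efficiently; each edge gets
    length 1/w (the pair(s) attaining d_max get no direct edge) and GE is
    computed over shortest paths.  Higher GE ⇔ tighter hub cluster ⇔ lower
    single-trial variability.  Invariant to uniform scaling of coordinates.
    """
    if hubs.n_selected < 2:
        raise ValueError("need at least 2 hubs")
    coords = points.coords[hubs.selected]
    d = squareform(pdist(coords))
    dmax = d.max()
    if dmax <= 0:
        warnings.warn("all hubs coincident: variability GE defined as 1")
        return 1.0
    w = 1.0 - d / dmax
    n = coords.shape[0]
    lengths = {}
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                lengths[(i, j)] = 1.0 / w[i, j]
    return _ge_from_lengths(n, lengths)
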