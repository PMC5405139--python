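"""Weighted-graph core: data model, distance transform, MST, shortest paths
and the network metrics used by the filtering and fingerprinting layers.

Conventions
-----------
A connectivity matrix ``W`` is an ``(N, N)`` symmetric array of coupling
strengths in ``[0, 1]`` with an exactly-zero diagonal.  Nodes are 0-based
integers internally; file formats carry 1-based labels (see :mod:`omstnet.io`).
The graph-theoretic distance between two directly coupled nodes is the
point-wise inverse ``1 / w`` (strong coupling = short distance); absent edges
(``w = 0``) have infinite distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _cs_shortest_path

__all__ = [
    "ConnectivityMatrix",
    "DistanceMatrix",
    "SpanningTree",
    "ShortestPathResult",
    "validate_weights",
    "as_weights",
    "to_distance",
    "kruskal_mst",
    "all_pairs_shortest_paths",
    "global_efficiency",
    "nodal_global_efficiency",
    "local_efficiency",
    "nodal_strength_clustering",
    "weighted_cost",
    "spl_length_distribution",
    "total_strength",
    "edge_list",
]

#: additive tolerance used when testing whether an edge lies on a shortest path
PATH_TOL = 1e-12


class GraphValidationError(ValueError):
    """Raised when a connectivity matrix violates its invariants."""


def validate_weights(W: np.ndarray, *, name: str = "weights") -> np.ndarray:
    """Validate and return a connectivity weight matrix as float64.

    Requires a square 2-D symmetric matrix with non-negative finite entries
    and a zero diagonal.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise GraphValidationError(f"{name} must be a square 2-D matrix, got shape {W.shape}")
    if W.shape[0] < 2:
        raise GraphValidationError(f"{name} needs at least 2 nodes, got {W.shape[0]}")
    if not np.isfinite(W).all():
        raise GraphValidationError(f"{name} contains non-finite entries")
    if (W < 0).any():
        i, j = np.argwhere(W < 0)[0]
        raise GraphValidationError(f"{name} has negative entry at ({i}, {j})")
    if not np.allclose(W, W.T, atol=0.0):
        raise GraphValidationError(f"{name} is not symmetric")
    if np.any(np.diag(W) != 0):
        raise GraphValidationError(f"{name} diagonal must be exactly zero")
    return W


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted functional connectivity graph over ``N`` nodes."""

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = validate_weights(self.weights)
        n = self.weights.shape[0]
        if not self.node_labels:
            self.node_labels = [f"n{i + 1}" for i in range(n)]
        if len(self.node_labels) != n:
            raise GraphValidationError(
                f"got {len(self.node_labels)} labels for {n} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_possible_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def normalized(self) -> "ConnectivityMatrix":
        """Return a copy max-normalized so the largest weight is 1."""
        mx = self.weights.max()
        W = self.weights / mx if mx > 0 else self.weights.copy()
        return ConnectivityMatrix(W, list(self.node_labels))


def as_weights(cm) -> np.ndarray:
    """Coerce a ConnectivityMatrix or array-like to a validated weight matrix."""
    if isinstance(cm, ConnectivityMatrix):
        return cm.weights
    return validate_weights(cm)


@dataclass
class DistanceMatrix:
    """Point-wise inverse of a connectivity matrix: ``d = 1/w``, inf off-edges."""

    distances: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.distances.shape[0]


@dataclass
class SpanningTree:
    """A spanning tree (or forest): unordered node pairs plus total distance."""

    edges: list[tuple[int, int]]
    total_distance: float

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ShortestPathResult:
    """All-pairs shortest path lengths and which direct edges they use."""

    spl: np.ndarray
    used_edge_mask: np.ndarray


def to_distance(cm) -> DistanceMatrix:
    """Map coupling strengths to travel distances (``d = 1/w``, inf for w = 0)."""
    W = as_weights(cm)
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D)


def edge_list(W: np.ndarray) -> list[tuple[int, int]]:
    """Upper-triangle positive-weight edges of ``W`` as sorted (i, j) pairs."""
    iu, ju = np.triu_indices(W.shape[0], k=1)
    keep = W[iu, ju] > 0
    return list(zip(iu[keep].tolist(), ju[keep].tolist()))


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


def kruskal_mst(dm: DistanceMatrix | np.ndarray, *, allow_forest: bool = False) -> SpanningTree:
    """Minimum spanning tree of a distance matrix by Kruskal's algorithm.

    Edges are considered in ascending ``(distance, i, j)`` order, which makes
    the result deterministic even with tied distances (the MST is unique only
    when all distances are unique).  Entries that are 0 (diagonal) or inf
    (absent edges) are skipped.

    Parameters
    ----------
    dm
        Distance matrix or raw ``(N, N)`` array of distances.
    allow_forest
        If True, return a minimum spanning forest when the finite-edge
        subgraph is disconnected instead of raising.
    """
    D = dm.distances if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = D[iu, ju]
    finite = np.isfinite(d)
    iu, ju, d = iu[finite], ju[finite], d[finite]
    order = np.lexsort((ju, iu, d))  # primary key distance, then (i, j)
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    total = 0.0
    for idx in order:
        a, b = int(iu[idx]), int(ju[idx])
        if uf.union(a, b):
            edges.append((a, b))
            total += float(d[idx])
            if len(edges) == n - 1:
                break
    if len(edges) < n - 1 and not allow_forest:
        raise GraphValidationError(
            "no spanning tree: finite-edge subgraph is disconnected"
        )
    return SpanningTree(edges, total)


def all_pairs_shortest_paths(dm: DistanceMatrix | np.ndarray) -> ShortestPathResult:
    """All-pairs shortest path lengths (Dijkstra) plus the used-edge mask.

    An edge (u, v) is marked used iff it lies on at least one shortest path,
    i.e. ``spl[i, u] + d[u, v] + spl[v, j] == spl[i, j]`` for some pair (i, j),
    tested with additive tolerance ``PATH_TOL``.
    """
    D = dm.distances if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = D.shape[0]
    finite = np.isfinite(D) & (D > 0)
    graph = csr_matrix((D[finite], np.nonzero(finite)), shape=(n, n))
    spl = _cs_shortest_path(graph, method="D", directed=False)
    np.fill_diagonal(spl, 0.0)

    used = np.zeros((n, n), dtype=bool)
    iu, ju = np.nonzero(np.triu(finite, k=1))
    for u, v in zip(iu, ju):
        # via[i, j] = best path length through the edge u-v (either direction)
        via = np.minimum(
            spl[:, u][:, None] + spl[v, :][None, :],
            spl[:, v][:, None] + spl[u, :][None, :],
        ) + D[u, v]
        if np.any(via <= spl + PATH_TOL):
            used[u, v] = used[v, u] = True
    return ShortestPathResult(spl, used)


def _efficiency_from_spl(spl: np.ndarray) -> np.ndarray:
    n = spl.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(spl > 0, 1.0 / np.where(spl > 0, spl, 1.0), 0.0)
    inv[~np.isfinite(spl)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_global_efficiency(cm) -> np.ndarray:
    """Per-node efficiency: mean inverse shortest path length to all others.

    Disconnected pairs contribute 0 (``1/inf``), the Latora–Marchiori
    convention.  The mean over nodes equals :func:`global_efficiency`.
    """
    W = as_weights(cm)
    spl = all_pairs_shortest_paths(to_distance(W)).spl
    return _efficiency_from_spl(spl)


def global_efficiency(cm) -> float:
    """Global efficiency GE = (1/N) Σ_i Σ_{j≠i} d_ij^{-1} / (N−1) ∈ [0, 1]."""
    return float(nodal_global_efficiency(cm).mean())


def local_efficiency(cm) -> np.ndarray:
    """Per-node local efficiency: GE of the weighted neighbour-induced subgraph.

    Nodes with fewer than two neighbours get 0.
    """
    W = as_weights(cm)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(W[i] > 0)[0]
        if nbrs.size < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        if not sub.any():
            continue
        spl = all_pairs_shortest_paths(to_distance(sub)).spl
        out[i] = _efficiency_from_spl(spl).mean()
    return out


def nodal_strength_clustering(cm) -> tuple[np.ndarray, np.ndarray]:
    """Node strength (row sums) and Onnela weighted clustering coefficients.

    The clustering coefficient uses the geometric mean of triangle weights
    normalized by the maximum weight in the graph (Onnela form), as computed
    by networkx.
    """
    W = as_weights(cm)
    strength = W.sum(axis=1)
    G = nx.from_numpy_array(W)
    cc = nx.clustering(G, weight="weight")
    clustering = np.array([cc[i] for i in range(W.shape[0])])
    return strength, clustering


def total_strength(cm) -> float:
    """Sum of weights over unordered node pairs of the full graph."""
    W = as_weights(cm)
    return float(W.sum() / 2.0)


def weighted_cost(selected_edges: Iterable[tuple[int, int]], cm) -> float:
    """Cost of an edge selection: retained weight / total weight of the graph.

    ``selected_edges`` are unordered node pairs that must exist (w > 0) in
    ``cm``; sums are over unordered pairs so Cost ∈ [0, 1].
    """
    W = as_weights(cm)
    denom = total_strength(W)
    num = 0.0
    for u, v in selected_edges:
        w = W[u, v]
        if w <= 0:
            raise GraphValidationError(f"edge ({u}, {v}) is not present in the graph")
        num += float(w)
    return num / denom


def spl_length_distribution(cm, bins: int = 20) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of finite shortest-path lengths over unordered node pairs.

    Returns ``(counts, bin_edges, values)`` where ``values`` is the raw
    multiset of finite upper-triangle SPLs.  All-infinite SPL (empty graph)
    yields an empty histogram with a warning.
    """
    W = as_weights(cm)
    spl = all_pairs_shortest_paths(to_distance(W)).spl
    iu, ju = np.triu_indices(W.shape[0], k=1)
    vals = spl[iu, ju]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn("graph has no finite shortest paths; empty SPL histogram")
        return np.zeros(bins, dtype=int), np.linspace(0, 1, bins + 1), vals
    counts, edges = np.histogram(vals, bins=bins)
    return counts, edges, vals
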