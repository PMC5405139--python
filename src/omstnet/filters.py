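"""Topological filtering of weighted connectivity graphs.

Six thresholding schemes are provided, centred on the orthogonal-minimal-
spanning-tree (OMST) scheme: successive MSTs of the inverse-weight graph are
extracted, each orthogonal (edge-disjoint) to all earlier ones, and their
edges are aggregated one at a time while tracking the global-cost-efficiency
quality function

    J = GE - Cost

where GE is the global efficiency of the partially aggregated graph and Cost
is the sum of retained weights divided by the total strength of the original
graph.  The retained backbone is the aggregation prefix that maximizes J
(never less than the complete first MST, so the result is connected).

The comparison schemes are: an absolute-threshold sweep maximizing the same J
(`gce_sweep_filter`), the union of shortest-path edges (`uspt_filter`), and
the three arbitrary schemes (absolute / proportional / mean-degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .graph import (
    GraphValidationError,
    ShortestPathResult,
    SpanningTree,
    all_pairs_shortest_paths,
    as_weights,
    edge_list,
    kruskal_mst,
    nodal_global_efficiency,
    to_distance,
    total_strength,
)

__all__ = [
    "OMSTDecomposition",
    "QualityCurve",
    "FilteredGraph",
    "omst_decompose",
    "omst_filter",
    "gce_sweep_filter",
    "uspt_filter",
    "arbitrary_filter",
    "match_threshold_by_frobenius",
    "FILTER_SCHEMES",
]

ArbitraryScheme = Literal["absolute", "proportional", "mean_degree"]


@dataclass
class OMSTDecomposition:
    """Ordered edge-disjoint spanning trees extracted from one graph."""

    trees: list[SpanningTree]
    aggregation_order: list[tuple[int, int]]
    rounds_extracted: int


@dataclass
class QualityCurve:
    """Per-step Cost, GE and J = GE − Cost along an aggregation sequence."""

    cost: np.ndarray
    global_efficiency: np.ndarray
    J: np.ndarray
    argmax_index: int


@dataclass
class FilteredGraph:
    """A filtered graph: original weights on retained edges, 0 elsewhere."""

    weights: np.ndarray
    scheme: str
    parameters: dict = field(default_factory=dict)
    quality: QualityCurve | None = None

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))


def _omst_rounds(
    D: np.ndarray, allow_forest: bool
) -> Iterator[SpanningTree]:
    """Yield successive edge-disjoint minimum spanning trees (or forests).

    After each round the accepted edges are set to +inf so the next MST is
    orthogonal to all previous ones.  Stops when the residual finite-edge
    subgraph can no longer span (strict mode) or has no edges (forest mode).
    """
    D = D.copy()
    first = True
    while True:
        try:
            tree = kruskal_mst(D, allow_forest=allow_forest)
        except GraphValidationError:
            if first:
                raise
            return
        if not tree.edges:
            return
        yield tree
        first = False
        for u, v in tree.edges:
            D[u, v] = D[v, u] = np.inf


def omst_decompose(
    cm, max_rounds: int | None = None, *, allow_forest: bool = False
) -> OMSTDecomposition:
    """Extract orthogonal MSTs of the inverse-weight graph.

    Parameters
    ----------
    cm
        Connectivity matrix (must be connected on its positive weights
        unless ``allow_forest``).
    max_rounds
        Cap on the number of rounds; default ``E // (N − 1)`` where E is the
        number of positive-weight edges.
    allow_forest
        Extract spanning forests per round on disconnected graphs (used for
        statistically masked window-graphs that may split into components).

    Returns
    -------
    OMSTDecomposition
        Trees in extraction order plus the flat edge aggregation order
        (round order, within-round Kruskal acceptance order).
    """
    W = as_weights(cm)
    n = W.shape[0]
    n_edges = len(edge_list(W))
    if max_rounds is None:
        max_rounds = max(1, n_edges // (n - 1))
    D = to_distance(W).distances
    trees: list[SpanningTree] = []
    order: list[tuple[int, int]] = []
    for tree in _omst_rounds(D, allow_forest):
        trees.append(tree)
        order.extend(tree.edges)
        if len(trees) >= max_rounds:
            break
    return OMSTDecomposition(trees, order, len(trees))


def _quality_along(
    W: np.ndarray, order: list[tuple[int, int]], denom: float
) -> QualityCurve:
    """Evaluate Cost, GE and J after each edge addition along ``order``."""
    n = W.shape[0]
    sel = np.zeros_like(W)
    cost = np.empty(len(order))
    ge = np.empty(len(order))
    running = 0.0
    for k, (u, v) in enumerate(order):
        sel[u, v] = sel[v, u] = W[u, v]
        running += W[u, v]
        cost[k] = running / denom
        spl = all_pairs_shortest_paths(to_distance(sel)).spl
        with np.errstate(divide="ignore"):
            inv = np.where(spl > 0, 1.0 / np.where(spl > 0, spl, 1.0), 0.0)
        inv[~np.isfinite(spl)] = 0.0
        np.fill_diagonal(inv, 0.0)
        ge[k] = inv.sum() / (n * (n - 1))
    J = ge - cost
    return QualityCurve(cost, ge, J, int(np.argmax(J)))


def omst_filter(
    cm,
    max_rounds: int | None = None,
    *,
    allow_forest: bool = False,
    early_stop: bool = True,
) -> FilteredGraph:
    """OMST data-driven filter: keep the J-maximizing OMST aggregation prefix.

    Edges are aggregated over successive orthogonal MSTs (round order,
    within-round Kruskal acceptance order); after each addition Cost, GE and
    J = GE − Cost are recorded.  The retained prefix is the first global
    maximizer of J, floored at the complete first MST so the output is always
    a connected backbone.  With ``early_stop`` the extraction halts after a
    full round that fails to improve the best J (late rounds cannot win: Cost
    grows monotonically while GE is bounded by 1).
    """
    W = as_weights(cm)
    n = W.shape[0]
    denom = total_strength(W)
    n_edges = len(edge_list(W))
    if max_rounds is None:
        max_rounds = max(1, n_edges // (n - 1))

    D = to_distance(W).distances
    trees: list[SpanningTree] = []
    order: list[tuple[int, int]] = []
    cost_parts: list[np.ndarray] = []
    ge_parts: list[np.ndarray] = []
    best_J = -np.inf
    sel = np.zeros_like(W)
    running = 0.0
    for tree in _omst_rounds(D, allow_forest):
        trees.append(tree)
        costs = np.empty(len(tree.edges))
        ges = np.empty(len(tree.edges))
        for k, (u, v) in enumerate(tree.edges):
            sel[u, v] = sel[v, u] = W[u, v]
            running += W[u, v]
            costs[k] = running / denom
            spl = all_pairs_shortest_paths(to_distance(sel)).spl
            with np.errstate(divide="ignore"):
                inv = np.where(spl > 0, 1.0 / np.where(spl > 0, spl, 1.0), 0.0)
            inv[~np.isfinite(spl)] = 0.0
            np.fill_diagonal(inv, 0.0)
            ges[k] = inv.sum() / (n * (n - 1))
        order.extend(tree.edges)
        cost_parts.append(costs)
        ge_parts.append(ges)
        round_best = float(np.max(ges - costs))
        if len(trees) >= max_rounds:
            break
        if early_stop and len(trees) > 1 and round_best <= best_J:
            break
        best_J = max(best_J, round_best)

    cost = np.concatenate(cost_parts)
    ge = np.concatenate(ge_parts)
    J = ge - cost
    curve = QualityCurve(cost, ge, J, int(np.argmax(J)))

    floor = len(trees[0].edges)  # never drop below the complete 1st MST
    n_keep = max(curve.argmax_index + 1, floor)
    out = np.zeros_like(W)
    for u, v in order[:n_keep]:
        out[u, v] = out[v, u] = W[u, v]
    return FilteredGraph(
        out,
        "omst",
        {
            "n_edges": n_keep,
            "rounds_extracted": len(trees),
            "max_J": float(J[curve.argmax_index]),
            "aggregation_order": order,
        },
        curve,
    )


def gce_sweep_filter(cm, step: float = 0.01) -> FilteredGraph:
    """Absolute-threshold sweep maximizing J = GE − Cost.

    For each threshold τ from the smallest to the largest positive weight in
    increments of ``step``, edges with w ≥ τ are retained and J evaluated with
    the weighted cost (retained weight / total strength), so the curve is
    commensurable with the OMST quality curve.  The binary-cost variant
    (retained edges / possible edges) is reported alongside.  Returns the
    filtered graph at the J-maximizing τ (first on ties).
    """
    if step <= 0:
        raise GraphValidationError("sweep step must be positive")
    W = as_weights(cm)
    n = W.shape[0]
    denom = total_strength(W)
    e_possible = n * (n - 1) // 2
    pos = W[np.triu_indices(n, k=1)]
    pos = pos[pos > 0]
    if pos.size == 0:
        raise GraphValidationError("graph has no positive edges")
    taus = np.arange(pos.min(), pos.max() + step / 2.0, step)
    cost_w = np.empty(taus.size)
    cost_b = np.empty(taus.size)
    ge = np.empty(taus.size)
    for k, tau in enumerate(taus):
        mask = W >= tau
        sel = np.where(mask, W, 0.0)
        np.fill_diagonal(sel, 0.0)
        cost_w[k] = sel.sum() / 2.0 / denom
        cost_b[k] = np.count_nonzero(np.triu(sel, k=1)) / e_possible
        spl = all_pairs_shortest_paths(to_distance(sel)).spl
        with np.errstate(divide="ignore"):
            inv = np.where(spl > 0, 1.0 / np.where(spl > 0, spl, 1.0), 0.0)
        inv[~np.isfinite(spl)] = 0.0
        np.fill_diagonal(inv, 0.0)
        ge[k] = inv.sum() / (n * (n - 1))
    J = ge - cost_w
    best = int(np.argmax(J))
    tau_star = float(taus[best])
    sel = np.where(W >= tau_star, W, 0.0)
    np.fill_diagonal(sel, 0.0)
    curve = QualityCurve(cost_w, ge, J, best)
    return FilteredGraph(
        sel,
        "gce",
        {
            "threshold": tau_star,
            "step": step,
            "thresholds": taus,
            "binary_cost": cost_b,
            "J_binary": ge - cost_b,
            "max_J": float(J[best]),
        },
        curve,
    )


def uspt_filter(cm) -> tuple[FilteredGraph, ShortestPathResult]:
    """Keep edges lying on at least one shortest path of the inverse graph.

    Returns the filtered graph plus the all-pairs shortest-path result whose
    ``spl`` matrix is the derived distance matrix.
    """
    W = as_weights(cm)
    res = all_pairs_shortest_paths(to_distance(W))
    sel = np.where(res.used_edge_mask, W, 0.0)
    return FilteredGraph(sel, "uspt", {}), res


def _strongest_k(W: np.ndarray, k: int) -> np.ndarray:
    """Filtered matrix keeping the k strongest upper-triangle edges.

    Ties at the cutoff weight resolve in ascending (i, j) order so exactly k
    edges are retained whenever k positive edges exist.
    """
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))
    keep = order[: min(k, order.size)]
    out = np.zeros_like(W)
    out[iu[keep], ju[keep]] = w[keep]
    return out + out.T


def arbitrary_filter(cm, scheme: ArbitraryScheme, param: float) -> FilteredGraph:
    """Arbitrary thresholding: absolute / proportional / mean-degree.

    - ``absolute``: keep edges with w ≥ τ, τ ∈ [0, 1];
    - ``proportional``: keep the round(p/100 · E) strongest edges,
      p ∈ (0, 100], E = N(N−1)/2;
    - ``mean_degree``: keep the ⌈k·N/2⌉ strongest edges, k ∈ [1, N−1],
      realizing a mean degree of about k.
    """
    W = as_weights(cm)
    n = W.shape[0]
    e_possible = n * (n - 1) // 2
    if scheme == "absolute":
        if not 0.0 <= param <= 1.0:
            raise GraphValidationError(f"absolute threshold must be in [0, 1], got {param}")
        sel = np.where(W >= param, W, 0.0)
        np.fill_diagonal(sel, 0.0)
    elif scheme == "proportional":
        if not 0.0 < param <= 100.0:
            raise GraphValidationError(f"proportional % must be in (0, 100], got {param}")
        k = int(round(param / 100.0 * e_possible))
        sel = _strongest_k(W, k)
    elif scheme == "mean_degree":
        if not 1.0 <= param <= n - 1:
            raise GraphValidationError(f"mean degree must be in [1, N-1], got {param}")
        k = int(np.ceil(param * n / 2.0))
        sel = _strongest_k(W, k)
    else:
        raise GraphValidationError(f"unknown scheme {scheme!r}")
    return FilteredGraph(sel, scheme, {"param": float(param)})


def _default_grid(scheme: ArbitraryScheme, n: int, grid_step: float | None) -> np.ndarray:
    if scheme == "absolute":
        step = 0.01 if grid_step is None else grid_step
        return np.arange(0.0, 1.0 + step / 2.0, step)
    if scheme == "proportional":
        step = 1.0 if grid_step is None else grid_step
        return np.arange(step, 100.0 + step / 2.0, step)
    if scheme == "mean_degree":
        step = 0.1 if grid_step is None else grid_step
        return np.arange(1.0, (n - 1) + step / 2.0, step)
    raise GraphValidationError(f"unknown scheme {scheme!r}")


def match_threshold_by_frobenius(
    cm,
    reference: FilteredGraph | np.ndarray,
    scheme: ArbitraryScheme,
    grid_step: float | None = None,
) -> float:
    """Arbitrary-scheme parameter best matching a reference filtered graph.

    Scans the scheme's parameter grid (default steps: 0.01 absolute, 1%
    proportional, 0.1 mean degree) and returns the value whose filtered
    output minimizes the Frobenius norm of (filtered − reference); the first
    grid point wins ties.
    """
    W = as_weights(cm)
    ref = reference.weights if isinstance(reference, FilteredGraph) else np.asarray(reference, float)
    if ref.shape != W.shape:
        raise GraphValidationError("reference and input dimensions differ")
    grid = _default_grid(scheme, W.shape[0], grid_step)
    if grid.size == 0:
        raise GraphValidationError("empty parameter grid")
    best_param, best_norm = None, np.inf
    for param in grid:
        out = arbitrary_filter(W, scheme, float(param)).weights
        nrm = float(np.linalg.norm(out - ref))
        if nrm < best_norm - 1e-15:
            best_param, best_norm = float(param), nrm
    return best_param


def _scheme_filter(W, scheme: str, param: float | None = None, **kw) -> FilteredGraph:
    """Dispatch a scheme name to its filter (used by the CLI and NMTS layer)."""
    if scheme == "omst":
        return omst_filter(W, **kw)
    if scheme == "gce":
        return gce_sweep_filter(W, **({"step": param} if param else {}))
    if scheme == "uspt":
        return uspt_filter(W)[0]
    if scheme in ("absolute", "proportional", "mean_degree"):
        if param is None:
            raise GraphValidationError(f"scheme {scheme!r} requires a parameter")
        return arbitrary_filter(W, scheme, param)
    raise GraphValidationError(f"unknown scheme {scheme!r}")


FILTER_SCHEMES = ("omst", "gce", "uspt", "absolute", "proportional", "mean_degree")
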