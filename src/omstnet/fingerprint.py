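"""Subject fingerprinting from network-metric time series (NMTS).

A filtered dynamic connectivity tensor yields, per band and node, a time
series of a nodal network metric (nodal global efficiency by default).  Each
series is split into two halves, delay-embedded (Ragwitz criterion:
local-constant one-step prediction error minimized over an embedding grid)
into a trajectory cloud, and pairs of clouds are compared with a multivariate
Wald–Wolfowitz runs test: build the Euclidean minimum spanning tree of the
pooled points, count runs R = (# cross-sample MST edges) + 1, standardize via
the Friedman–Rafsky moments

    E[R] = 2mn/N + 1
    Var[R] = (2mn / (N(N−1))) [ (2mn − N)/N
             + (C − N + 2)(N(N−1) − 4mn + 2) / ((N−2)(N−3)) ]

with N = m + n and C the number of MST edge pairs sharing a node, giving the
dissimilarity index w = (R − E[R]) / sqrt(Var[R]) and the one-sided distance
w_dist = |w|·H(−w) (only a deficit of runs marks dissimilarity).  A query
half-series is attributed to the subject whose candidate half is nearest in
w_dist, per feature, with a majority vote across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform, pdist

from . import graph as _g
from .dynamics import TVGraphTensor
from .filters import _scheme_filter

__all__ = [
    "NMTSRecord",
    "EmbeddingSpec",
    "TrajectoryCloud",
    "WWStatistics",
    "IdentificationReport",
    "compute_nmts",
    "split_halves",
    "ragwitz_embed",
    "delay_embed",
    "ww_dissimilarity",
    "identify_subject",
    "select_features",
    "recognition_rate",
    "confusion_matrix_from_predictions",
]

NODAL_METRICS = ("nodal_GE", "strength", "clustering", "local_efficiency")
NETWORK_METRICS = ("network_GE",)


@dataclass
class NMTSRecord:
    """One network-metric time series: (subject, band, node) → values."""

    subject_id: str
    band: str
    node: int
    metric: str
    series: np.ndarray


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: dimension ``d_e`` and delay ``d_t``."""

    d_e: int
    d_t: int

    def __post_init__(self) -> None:
        if self.d_e < 1 or self.d_t < 1:
            raise ValueError("embedding dimension and delay must be >= 1")


@dataclass
class TrajectoryCloud:
    """Delay vectors X_t = [x(t), x(t+d_t), ..., x(t+d_t(d_e−1))]."""

    points: np.ndarray
    spec: EmbeddingSpec

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class WWStatistics:
    """Runs count with Friedman–Rafsky moments and the dissimilarity index."""

    R: int
    E_R: float
    Var_R: float
    w: float
    w_dist: float


@dataclass
class IdentificationReport:
    """Confusion matrix, selected features and overall recognition rate."""

    CM: np.ndarray
    subjects: list[str]
    selected_features: list[tuple[str, int]]
    recognition_rate: float


def _window_metric(W: np.ndarray, metric: str) -> np.ndarray | float:
    if not W.any():
        warnings.warn("all-zero window slice; metric set to 0")
        n = W.shape[0]
        return 0.0 if metric == "network_GE" else np.zeros(n)
    if metric == "nodal_GE":
        return _g.nodal_global_efficiency(W)
    if metric == "network_GE":
        return _g.global_efficiency(W)
    if metric == "strength":
        return _g.nodal_strength_clustering(W)[0]
    if metric == "clustering":
        return _g.nodal_strength_clustering(W)[1]
    if metric == "local_efficiency":
        return _g.local_efficiency(W)
    raise ValueError(f"unknown metric {metric!r}")


def compute_nmts(
    tensor: TVGraphTensor,
    filter_scheme: str | None = "omst",
    metric: str = "nodal_GE",
    *,
    filter_param: float | None = None,
    subject_id: str = "subject",
) -> list[NMTSRecord]:
    """Network-metric time series from a masked dynamic tensor.

    Per band and window the (already statistically masked) iPLV slice is
    topologically filtered with ``filter_scheme`` (None = no filtering) and
    the requested metric computed; nodal metrics yield one series per node
    and band, ``network_GE`` one series per band.  Masked window graphs may
    be disconnected, so the OMST scheme runs in its spanning-forest mode
    here; all-zero slices yield metric 0 with a warning.
    """
    records: list[NMTSRecord] = []
    n = tensor.n_nodes
    for b, band in enumerate(tensor.bands):
        slices = tensor.band_slices(b)
        per_window = []
        for W in slices:
            if filter_scheme is not None and W.any():
                kw = {"allow_forest": True} if filter_scheme == "omst" else {}
                W = _scheme_filter(W, filter_scheme, filter_param, **kw).weights
            per_window.append(_window_metric(W, metric))
        if metric == "network_GE":
            series = np.asarray(per_window, dtype=float)
            records.append(NMTSRecord(subject_id, band.name, -1, metric, series))
        else:
            arr = np.stack(per_window)  # (windows, nodes)
            for node in range(n):
                records.append(
                    NMTSRecord(subject_id, band.name, node, metric, arr[:, node])
                )
    return records


def split_halves(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a series into two contiguous halves (extra sample to the first)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series too short to split")
    half = (x.size + 1) // 2
    return x[:half], x[half:]


def delay_embed(series: np.ndarray, spec: EmbeddingSpec) -> TrajectoryCloud:
    """Build the delay-vector cloud of a series for a given embedding."""
    x = np.asarray(series, dtype=float)
    span = (spec.d_e - 1) * spec.d_t
    m = x.size - span
    if m < 1:
        raise ValueError(
            f"series of length {x.size} too short for d_e={spec.d_e}, d_t={spec.d_t}"
        )
    idx = np.arange(m)[:, None] + np.arange(spec.d_e)[None, :] * spec.d_t
    return TrajectoryCloud(x[idx], spec)


def _prediction_error(x: np.ndarray, spec: EmbeddingSpec, k: int) -> float:
    """Normalized local-constant one-step prediction error of an embedding."""
    span = (spec.d_e - 1) * spec.d_t
    m = x.size - span - 1  # need one future sample per vector
    if m < k + 2:
        return np.inf
    idx = np.arange(m)[:, None] + np.arange(spec.d_e)[None, :] * spec.d_t
    pts = x[idx]
    target = x[span + 1 + np.arange(m)]
    tree = cKDTree(pts)
    _, nbr = tree.query(pts, k=k + 1)  # first neighbour is the point itself
    pred = target[nbr[:, 1:]].mean(axis=1)
    denom = x.std()
    return float(np.sqrt(np.mean((pred - target) ** 2)) / denom)


def ragwitz_embed(
    series: np.ndarray,
    *,
    d_e_grid: range = range(1, 9),
    d_t_grid: range = range(1, 11),
    k: int = 5,
) -> tuple[EmbeddingSpec, TrajectoryCloud]:
    """Select (d_e, d_t) by the Ragwitz criterion and build the cloud.

    Minimizes the local-constant (k-nearest-neighbour mean) one-step
    prediction error over the candidate grid; ties go to the smallest d_e,
    then the smallest d_t.  Raises on a constant (degenerate) series.
    """
    x = np.asarray(series, dtype=float)
    if x.std() == 0:
        raise ValueError("degenerate series: constant input cannot be embedded")
    best: tuple[float, int, int] | None = None
    for d_e in d_e_grid:
        for d_t in d_t_grid:
            err = _prediction_error(x, EmbeddingSpec(d_e, d_t), k)
            key = (err, d_e, d_t)
            if best is None or key < best:
                best = key
    spec = EmbeddingSpec(best[1], best[2])
    return spec, delay_embed(x, spec)


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Perturb exact duplicate points by an index-keyed 1e-12 jitter.

    Keeps the Euclidean MST unique and the runs count well defined.
    """
    pts = np.array(points, dtype=float)
    _, inverse, counts = np.unique(
        pts, axis=0, return_inverse=True, return_counts=True
    )
    dup = counts[inverse] > 1
    if dup.any():
        pts[dup, 0] += 1e-12 * np.flatnonzero(dup)
    return pts


def _prim_mst_edges(dist: np.ndarray) -> list[tuple[int, int]]:
    """Exact MST edges of a dense symmetric distance matrix (Prim, O(N²))."""
    N = dist.shape[0]
    in_tree = np.zeros(N, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    parent = np.zeros(N, dtype=int)
    best[0] = np.inf
    edges: list[tuple[int, int]] = []
    for _ in range(N - 1):
        v = int(np.argmin(best))
        edges.append((int(parent[v]), v))
        in_tree[v] = True
        best[v] = np.inf
        closer = dist[v] < best
        closer &= ~in_tree
        parent[closer] = v
        best[closer] = dist[v][closer]
    return edges


def ww_dissimilarity(X: TrajectoryCloud | np.ndarray, Y: TrajectoryCloud | np.ndarray) -> WWStatistics:
    """Multivariate Wald–Wolfowitz runs statistic between two point clouds."""
    xs = X.points if isinstance(X, TrajectoryCloud) else np.asarray(X, float)
    ys = Y.points if isinstance(Y, TrajectoryCloud) else np.asarray(Y, float)
    if xs.ndim == 1:
        xs = xs[:, None]
    if ys.ndim == 1:
        ys = ys[:, None]
    m, n = xs.shape[0], ys.shape[0]
    if m < 5 or n < 5:
        raise ValueError("each sample needs at least 5 points")
    pooled = _dedupe(np.vstack([xs, ys]))
    labels = np.concatenate([np.zeros(m, dtype=int), np.ones(n, dtype=int)])
    dist = squareform(pdist(pooled))
    edges = _prim_mst_edges(dist)

    N = m + n
    eu = np.array([e[0] for e in edges])
    ev = np.array([e[1] for e in edges])
    cross = int((labels[eu] != labels[ev]).sum())
    R = cross + 1
    deg = np.bincount(np.concatenate([eu, ev]), minlength=N)
    C = float((deg * (deg - 1)).sum() / 2.0)

    E_R = 2.0 * m * n / N + 1.0
    var = (
        2.0 * m * n / (N * (N - 1.0))
        * (
            (2.0 * m * n - N) / N
            + (C - N + 2.0) * (N * (N - 1.0) - 4.0 * m * n + 2.0)
            / ((N - 2.0) * (N - 3.0))
        )
    )
    w = (R - E_R) / np.sqrt(var)
    w_dist = abs(w) if w < 0 else 0.0
    return WWStatistics(int(R), float(E_R), float(var), float(w), float(w_dist))


FeatureKey = tuple[str, int]  # (band name, node index)
Database = dict[str, dict[FeatureKey, tuple[np.ndarray, np.ndarray]]]


def _embed_pair(
    query: np.ndarray, candidate: np.ndarray, spec: EmbeddingSpec
) -> float:
    """w_dist between query and candidate halves embedded with a shared spec."""
    return ww_dissimilarity(delay_embed(query, spec), delay_embed(candidate, spec)).w_dist


def identify_subject(
    query: dict[FeatureKey, np.ndarray],
    database: Database,
    features: list[FeatureKey] | None = None,
    *,
    embedding: EmbeddingSpec | None = None,
    exclude_first_half_of: str | None = None,
) -> str:
    """Predict the subject a query set of NMTS halves belongs to.

    Per feature the query half is embedded (Ragwitz-optimized unless a fixed
    ``embedding`` is given), every candidate half in the database is embedded
    with the query's parameters (shared space), and the candidate with the
    smallest WW distance votes for its subject.  The prediction is the
    majority vote across features; ties resolve to the subject with the
    smallest mean w_dist.  ``exclude_first_half_of`` removes the query's own
    half from its subject's candidates (the usual split-half protocol).
    """
    if not query:
        raise ValueError("empty feature set")
    features = features if features is not None else sorted(query.keys())
    subjects = sorted(database.keys())
    votes: dict[str, int] = {s: 0 for s in subjects}
    dist_sums: dict[str, float] = {s: 0.0 for s in subjects}
    dist_counts: dict[str, int] = {s: 0 for s in subjects}
    for feat in features:
        series = query[feat]
        if embedding is None:
            spec, _ = ragwitz_embed(series)
        else:
            spec = embedding
        best_subj, best_d = None, np.inf
        for subj in subjects:
            halves = database[subj][feat]
            pool = list(halves)
            if subj == exclude_first_half_of:
                pool = [halves[1]]
            for cand in pool:
                d = _embed_pair(series, cand, spec)
                dist_sums[subj] += d
                dist_counts[subj] += 1
                if d < best_d:
                    best_subj, best_d = subj, d
        votes[best_subj] += 1
    top = max(votes.values())
    tied = [s for s in subjects if votes[s] == top]
    if len(tied) == 1:
        return tied[0]
    return min(tied, key=lambda s: dist_sums[s] / max(1, dist_counts[s]))


def confusion_matrix_from_predictions(
    subjects: list[str], predictions: dict[str, str]
) -> np.ndarray:
    """Row-normalized confusion matrix (rows actual, columns predicted)."""
    idx = {s: i for i, s in enumerate(subjects)}
    cm = np.zeros((len(subjects), len(subjects)))
    for actual, predicted in predictions.items():
        cm[idx[actual], idx[predicted]] += 1.0
    sums = cm.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return cm / sums


def recognition_rate(CM: np.ndarray) -> float:
    """Recognition rate in percent: 100 × mean of the CM diagonal."""
    CM = np.asarray(CM, dtype=float)
    if CM.ndim != 2 or CM.shape[0] != CM.shape[1]:
        raise ValueError("confusion matrix must be square")
    return float(100.0 * np.mean(np.diag(CM)))


def _cohort_rate(
    database: Database,
    features: list[FeatureKey],
    embedding: EmbeddingSpec | None,
) -> tuple[float, np.ndarray]:
    """Split-half recognition rate using every subject's first half as query."""
    subjects = sorted(database.keys())
    preds = {}
    for subj in subjects:
        query = {f: database[subj][f][0] for f in features}
        preds[subj] = identify_subject(
            query, database, features, embedding=embedding, exclude_first_half_of=subj
        )
    cm = confusion_matrix_from_predictions(subjects, preds)
    return recognition_rate(cm), cm


def select_features(
    database: Database,
    max_features: int = 150,
    *,
    embedding: EmbeddingSpec | None = None,
) -> list[FeatureKey]:
    """Greedy forward feature selection maximizing split-half recognition.

    Starting from the empty set, repeatedly adds the (band, node) feature
    that most improves the in-sample recognition rate; stops when no feature
    improves it or ``max_features`` is reached.  Ties break on (band, node)
    order of the database's feature list.
    """
    subjects = sorted(database.keys())
    if len(subjects) < 2:
        raise ValueError("feature selection needs at least 2 subjects")
    all_feats = sorted(database[subjects[0]].keys())
    selected: list[FeatureKey] = []
    best_rate = -np.inf
    while len(selected) < max_features:
        best_feat, best_new = None, best_rate
        for feat in all_feats:
            if feat in selected:
                continue
            rate, _ = _cohort_rate(database, selected + [feat], embedding)
            if rate > best_new:
                best_feat, best_new = feat, rate
        if best_feat is None:
            break
        selected.append(best_feat)
        best_rate = best_new
    return selected


def identification_report(
    database: Database,
    features: list[FeatureKey] | None = None,
    *,
    embedding: EmbeddingSpec | None = None,
) -> IdentificationReport:
    """Full split-half identification over a cohort database."""
    subjects = sorted(database.keys())
    feats = features if features is not None else sorted(database[subjects[0]].keys())
    rate, cm = _cohort_rate(database, feats, embedding)
    return IdentificationReport(cm, subjects, list(feats), rate)
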