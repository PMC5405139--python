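"""Scikit-learn-style estimators wrapping the filtering and fingerprinting
methods, so they compose with pipelines and model selection.

The six thresholding schemes are stateless transformers over stacks of
connectivity matrices: ``transform`` maps ``(N, N)`` or ``(k, N, N)`` weight
arrays to their filtered counterparts (retained weights unchanged, zeros
elsewhere).  ``filter_graph`` exposes the rich per-graph result (quality
curve, parameters).  ``WWIdentifier`` is a nearest-neighbour classifier over
delay-embedded metric time series using the WW-test distance.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from . import filters as _f
from .fingerprint import EmbeddingSpec, delay_embed, ragwitz_embed, ww_dissimilarity
from .graph import validate_weights

__all__ = [
    "OMSTThreshold",
    "GCEThreshold",
    "ShortestPathThreshold",
    "ArbitraryThreshold",
    "WWIdentifier",
]


class _BaseGraphFilter(TransformerMixin, BaseEstimator):
    """Common machinery: validation and stack-wise transformation."""

    def fit(self, X, y=None):
        """Validate input shape; these filters carry no fitted state."""
        X = np.asarray(X, dtype=float)
        mats = X[None] if X.ndim == 2 else X
        for W in mats:
            validate_weights(W)
        self.n_nodes_ = mats.shape[-1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return self.filter_graph(X).weights
        return np.stack([self.filter_graph(W).weights for W in X])

    def filter_graph(self, W) -> _f.FilteredGraph:  # pragma: no cover - abstract
        raise NotImplementedError


class OMSTThreshold(_BaseGraphFilter):
    """Orthogonal-MST data-driven filter maximizing J = GE − Cost."""

    def __init__(self, max_rounds=None, allow_forest=False, early_stop=True):
        self.max_rounds = max_rounds
        self.allow_forest = allow_forest
        self.early_stop = early_stop

    def filter_graph(self, W) -> _f.FilteredGraph:
        return _f.omst_filter(
            W,
            self.max_rounds,
            allow_forest=self.allow_forest,
            early_stop=self.early_stop,
        )


class GCEThreshold(_BaseGraphFilter):
    """Absolute-threshold sweep maximizing the same J = GE − Cost."""

    def __init__(self, step=0.01):
        self.step = step

    def filter_graph(self, W) -> _f.FilteredGraph:
        return _f.gce_sweep_filter(W, self.step)


class ShortestPathThreshold(_BaseGraphFilter):
    """Keep the union of edges used by at least one shortest path."""

    def filter_graph(self, W) -> _f.FilteredGraph:
        return _f.uspt_filter(W)[0]


class ArbitraryThreshold(_BaseGraphFilter):
    """Absolute / proportional / mean-degree thresholding."""

    def __init__(self, scheme="proportional", param=10.0):
        self.scheme = scheme
        self.param = param

    def filter_graph(self, W) -> _f.FilteredGraph:
        return _f.arbitrary_filter(W, self.scheme, self.param)


class WWIdentifier(ClassifierMixin, BaseEstimator):
    """Nearest-neighbour subject classifier with the WW-test distance.

    ``fit`` stores a database of reference series: ``X`` is
    ``(n_samples, n_features, series_len)`` (each row one half-series per
    feature) with subject labels ``y``; a subject may contribute several
    rows (its halves).  ``predict`` embeds each query row per feature
    (Ragwitz-optimized unless ``embedding`` fixes (d_e, d_t)), embeds all
    references with the query's parameters, and votes the subject of the
    w_dist-nearest reference per feature, majority across features.
    """

    def __init__(self, embedding: EmbeddingSpec | None = None):
        self.embedding = embedding

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, n_features, series_len)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        out = []
        for row in X:
            votes: dict = {}
            dist_sums: dict = {}
            for f in range(row.shape[0]):
                series = row[f]
                spec = self.embedding or ragwitz_embed(series)[0]
                q_cloud = delay_embed(series, spec)
                best_label, best_d = None, np.inf
                for ref, label in zip(self.X_[:, f, :], self.y_):
                    d = ww_dissimilarity(q_cloud, delay_embed(ref, spec)).w_dist
                    dist_sums[label] = dist_sums.get(label, 0.0) + d
                    if d < best_d:
                        best_label, best_d = label, d
                votes[best_label] = votes.get(best_label, 0) + 1
            top = max(votes.values())
            tied = sorted(k for k, v in votes.items() if v == top)
            if len(tied) > 1:
                tied.sort(key=lambda s: dist_sums[s])
            out.append(tied[0])
        return np.asarray(out)
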