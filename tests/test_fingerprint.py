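"""NMTS extraction, delay embedding, WW runs test and identification."""

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from omstnet.dynamics import BandSpec, TVGraphTensor
from omstnet.fingerprint import (
    EmbeddingSpec,
    _prediction_error,
    _prim_mst_edges,
    compute_nmts,
    confusion_matrix_from_predictions,
    delay_embed,
    identify_subject,
    ragwitz_embed,
    recognition_rate,
    select_features,
    split_halves,
    ww_dissimilarity,
)
from omstnet.synth import CohortSpec, SynthGraphSpec, gen_backbone_graph, gen_cohort_nmts
from conftest import random_weight_matrix


def toy_tensor(slices, band_name="alpha1"):
    """Wrap a (windows, N, N) stack into a single-band tensor."""
    arr = np.asarray(slices, float)[None]
    nw = np.array([arr.shape[1]])
    times = np.arange(arr.shape[1], dtype=float)[None]
    return TVGraphTensor(arr, times, nw, (BandSpec(band_name, 8, 10),), 160.0)


class TestComputeNMTS:
    def test_static_tensor_gives_constant_series(self, rng):
        W = random_weight_matrix(rng, 6)
        tensor = toy_tensor([W] * 5)
        recs = compute_nmts(tensor, filter_scheme=None, metric="nodal_GE")
        assert len(recs) == 6
        for r in recs:
            assert np.ptp(r.series) == 0.0 and r.series.size == 5

    def test_nodal_mean_equals_network_series(self, rng):
        slices = [random_weight_matrix(rng, 5) for _ in range(4)]
        tensor = toy_tensor(slices)
        nodal = compute_nmts(tensor, None, "nodal_GE")
        net = compute_nmts(tensor, None, "network_GE")
        stacked = np.stack([r.series for r in nodal])
        np.testing.assert_allclose(stacked.mean(axis=0), net[0].series, atol=1e-12)

    def test_filter_schemes_change_the_series(self, rng):
        cm, _ = gen_backbone_graph(SynthGraphSpec(n_nodes=16, m_true=2, seed=3))
        slices = [cm.weights * s for s in (1.0, 0.95, 0.9)]
        tensor = toy_tensor(slices)
        a = np.stack([r.series for r in compute_nmts(tensor, "omst", "nodal_GE")])
        b = np.stack([r.series for r in compute_nmts(tensor, "proportional", "nodal_GE", filter_param=20.0)])
        assert not np.allclose(a, b)

    def test_all_zero_slice_warns_and_yields_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            recs = compute_nmts(toy_tensor([np.zeros((4, 4))]), None, "nodal_GE")
        assert all(r.series[0] == 0.0 for r in recs)


class TestSplitHalves:
    @pytest.mark.parametrize("length,first", [(100, 50), (101, 51)])
    def test_lengths(self, length, first):
        a, b = split_halves(np.arange(length))
        assert a.size == first and b.size == length - first
        np.testing.assert_array_equal(np.concatenate([a, b]), np.arange(length))


class TestEmbedding:
    def test_cloud_size_formula(self, rng):
        x = rng.standard_normal(100)
        cloud = delay_embed(x, EmbeddingSpec(4, 3))
        assert cloud.points.shape == (100 - 3 * 3, 4)
        np.testing.assert_array_equal(cloud.points[0], x[[0, 3, 6, 9]])

    def test_oscillation_needs_at_least_two_dimensions(self):
        x = np.sin(np.linspace(0, 24 * np.pi, 300)) + 0.05 * np.sin(
            np.linspace(0, 100, 300)
        )
        spec, _ = ragwitz_embed(x)
        assert spec.d_e >= 2

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ragwitz_embed(np.ones(50))

    def test_selection_matches_naive_grid_oracle(self, rng):
        # independent re-computation: brute-force neighbour search, no KD-tree
        x = rng.standard_normal(60).cumsum()
        k = 3
        best = None
        for d_e in range(1, 5):
            for d_t in range(1, 5):
                span = (d_e - 1) * d_t
                m = x.size - span - 1
                if m < k + 2:
                    err = np.inf
                else:
                    idx = np.arange(m)[:, None] + np.arange(d_e)[None, :] * d_t
                    pts = x[idx]
                    tgt = x[span + 1 + np.arange(m)]
                    preds = []
                    for i in range(m):
                        d = np.linalg.norm(pts - pts[i], axis=1)
                        d[i] = np.inf
                        preds.append(tgt[np.argsort(d, kind="stable")[:k]].mean())
                    err = float(np.sqrt(np.mean((np.array(preds) - tgt) ** 2)) / x.std())
                if best is None or (err, d_e, d_t) < best:
                    best = (err, d_e, d_t)
        spec, _ = ragwitz_embed(x, d_e_grid=range(1, 5), d_t_grid=range(1, 5), k=k)
        assert (spec.d_e, spec.d_t) == (best[1], best[2])


class TestWWTest:
    def test_separated_clusters_single_bridge(self, rng):
        a = rng.normal(0, 1, (50, 3))
        b = rng.normal(50, 1, (50, 3))
        st = ww_dissimilarity(a, b)
        assert st.R == 2
        assert st.w < 0 and st.w_dist > 3

    def test_heaviside_distance_definition(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, (30, 2))
            b = rng.normal(rng.uniform(0, 3), 1, (30, 2))
            st = ww_dissimilarity(a, b)
            assert st.w_dist == (abs(st.w) if st.w < 0 else 0.0)

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(0, 1, (40, 3))
        b = rng.normal(0.5, 1, (35, 3))
        s1, s2 = ww_dissimilarity(a, b), ww_dissimilarity(b, a)
        assert s1.R == s2.R and s1.w == pytest.approx(s2.w)

    def test_prim_mst_equals_scipy_reference(self, rng):
        for _ in range(10):
            P = rng.normal(0, 1, (int(rng.integers(10, 80)), 3))
            d = squareform(pdist(P))
            ours = sum(d[u, v] for u, v in _prim_mst_edges(d))
            assert ours == pytest.approx(minimum_spanning_tree(d).sum())

    def test_moments_match_label_permutation_oracle(self, rng):
        # E[R] and Var[R] over random labelings of a FIXED point set
        P = rng.normal(0, 1, (60, 3))
        edges = _prim_mst_edges(squareform(pdist(P)))
        eu = np.array([e[0] for e in edges])
        ev = np.array([e[1] for e in edges])
        m = 30
        Rs = []
        for _ in range(4000):
            labels = np.zeros(60, int)
            labels[rng.choice(60, m, replace=False)] = 1
            Rs.append((labels[eu] != labels[ev]).sum() + 1)
        Rs = np.array(Rs)
        st = ww_dissimilarity(P[:m], P[m:])
        assert st.E_R == pytest.approx(Rs.mean(), rel=0.02)
        assert st.Var_R == pytest.approx(Rs.var(), rel=0.15)

    def test_duplicate_points_handled(self):
        a = np.zeros((10, 2))
        b = np.ones((10, 2))
        st = ww_dissimilarity(a, b)
        assert st.R == 2

    def test_tiny_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            ww_dissimilarity(rng.normal(0, 1, (3, 2)), rng.normal(0, 1, (30, 2)))


class TestIdentification:
    def small_db(self, seed=0, **kw):
        return gen_cohort_nmts(CohortSpec(n_subjects=5, n_features=2, seed=seed, **kw))

    def test_exact_copy_always_self_matches(self):
        db = self.small_db()
        feats = sorted(db["S000"].keys())
        # replace target's second half by a copy of the first: zero distance
        db["S002"] = {f: (db["S002"][f][0], db["S002"][f][0].copy()) for f in feats}
        q = {f: db["S002"][f][0] for f in feats}
        assert identify_subject(q, db, feats, exclude_first_half_of="S002") == "S002"

    def test_small_cohort_identified(self):
        db = self.small_db()
        feats = sorted(db["S000"].keys())
        hits = sum(
            identify_subject({f: db[s][f][0] for f in feats}, db, feats,
                             exclude_first_half_of=s) == s
            for s in db
        )
        assert hits == 5

    def test_empty_feature_set_rejected(self):
        db = self.small_db()
        with pytest.raises(ValueError):
            identify_subject({}, db)

    def test_noise_accuracy_decreases(self):
        feats = None
        accs = []
        for sigma in (0.05, 1.5, 4.0):
            db = self.small_db(seed=7, noise_sigma=sigma)
            feats = sorted(db["S000"].keys())
            hits = sum(
                identify_subject({f: db[s][f][0] for f in feats}, db, feats,
                                 embedding=EmbeddingSpec(3, 1),
                                 exclude_first_half_of=s) == s
                for s in db
            )
            accs.append(hits)
        assert accs[0] >= accs[1] >= accs[2] or accs[0] > accs[2]


class TestFeatureSelection:
    def test_planted_discriminative_feature_found_first(self, rng):
        db = gen_cohort_nmts(CohortSpec(n_subjects=4, n_features=1, seed=1))
        feats = {}
        for s, sub in db.items():
            (h1, h2) = sub[("band0", 0)]
            noise = (rng.standard_normal(h1.size), rng.standard_normal(h2.size))
            feats[s] = {("band0", 0): noise, ("band0", 1): (h1, h2)}
        sel = select_features(feats, max_features=2, embedding=EmbeddingSpec(3, 1))
        assert sel[0] == ("band0", 1)
        assert len(sel) <= 2

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            select_features({"S0": {}}, 3)


class TestRecognitionRate:
    def test_reference_values(self):
        assert recognition_rate(np.eye(10)) == 100.0
        assert recognition_rate(np.full((4, 4), 0.25)) == 25.0
        cm = np.eye(10)
        cm[3, 3], cm[3, 4] = 0.0, 1.0
        assert recognition_rate(cm) == 90.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            recognition_rate(np.ones((2, 3)))

    def test_confusion_matrix_rows_normalized(self):
        cm = confusion_matrix_from_predictions(["a", "b"], {"a": "a", "b": "a"})
        np.testing.assert_allclose(cm.sum(axis=1), 1.0)


class TestWWIdentifierEstimator:
    def test_fit_predict_and_clone(self):
        from sklearn.base import clone
        from omstnet.estimators import WWIdentifier

        db = gen_cohort_nmts(CohortSpec(n_subjects=4, n_features=2, seed=2))
        subjects = sorted(db)
        feats = sorted(db[subjects[0]].keys())
        X, y, Q, qy = [], [], [], []
        for s in subjects:
            X.append([db[s][f][1] for f in feats])
            y.append(s)
            Q.append([db[s][f][0] for f in feats])
            qy.append(s)
        est = WWIdentifier(embedding=EmbeddingSpec(3, 1))
        assert clone(est).get_params()["embedding"] == EmbeddingSpec(3, 1)
        est.fit(np.array(X), np.array(y))
        pred = est.predict(np.array(Q))
        assert (pred == np.array(qy)).mean() == 1.0
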