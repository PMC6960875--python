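"""Eigen-feature pipeline: resampling, flattening, projection, 1-NN."""

import numpy as np
import pytest

from headgest import (
    PCAClassifier,
    SpatialSequence,
    TwoStagePCAClassifier,
    fit_projection,
    flatten,
    nn_classify,
    project,
    resample,
)
from headgest.pca import unflatten


def great_circle_arc(n, span=np.pi / 2):
    """Analytic arc from [0,0,1] toward [1,0,0]."""
    t = np.linspace(0, span, n)
    return SpatialSequence(
        vectors=np.column_stack([np.sin(t), np.zeros(n), np.cos(t)])
    )


class TestResample:
    def test_constant_sequence(self):
        seq = SpatialSequence(vectors=np.tile([0.0, 0.0, 1.0], (5, 1)))
        out = resample(seq, 12)
        assert len(out) == 12
        assert np.allclose(out.vectors, [0, 0, 1])

    def test_own_length_is_identity(self, rng):
        v = rng.normal(size=(20, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        seq = SpatialSequence(vectors=v)
        assert np.allclose(resample(seq, 20).vectors, v, atol=1e-9)

    def test_endpoints_preserved(self):
        arc = great_circle_arc(17)
        out = resample(arc, 50)
        assert np.allclose(out.vectors[0], arc.vectors[0], atol=1e-12)
        assert np.allclose(out.vectors[-1], arc.vectors[-1], atol=1e-12)

    def test_arc_upsampling_matches_analytic_curve(self):
        out = resample(great_circle_arc(50), 100)
        t = np.linspace(0, np.pi / 2, 100)
        analytic = np.column_stack([np.sin(t), np.zeros(100), np.cos(t)])
        assert np.abs(out.vectors - analytic).max() < 1e-3

    def test_output_unit_norm(self):
        out = resample(great_circle_arc(9), 40)
        assert np.allclose(np.linalg.norm(out.vectors, axis=1), 1.0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            resample(SpatialSequence(vectors=[[0, 0, 1.0]]), 10)


class TestFlatten:
    def test_column_major_order(self):
        seq = SpatialSequence(vectors=[[1.0, 0, 0], [0, 1.0, 0]])
        assert np.array_equal(flatten(seq), [1, 0, 0, 1, 0, 0])

    def test_length_is_three_m(self, rng):
        v = rng.normal(size=(13, 3))
        assert flatten(SpatialSequence(vectors=v)).shape == (39,)

    def test_roundtrip(self, rng):
        v = rng.normal(size=(11, 3))
        assert np.array_equal(unflatten(flatten(v)), v)


class TestFitProjectProject:
    @pytest.fixture
    def training(self, rng):
        return rng.normal(size=(40, 12))

    def test_mean_projects_to_zero(self, training):
        p = fit_projection(training, k=4)
        assert np.allclose(project(p.mean_vector, p), 0.0, atol=1e-12)

    def test_rows_orthonormal_eigenvalues_descending(self, training):
        p = fit_projection(training, k=12)
        assert np.allclose(p.eigenvectors @ p.eigenvectors.T, np.eye(12), atol=1e-9)
        assert np.all(np.diff(p.eigenvalues) <= 1e-12)
        assert np.all(p.eigenvalues >= -1e-9)

    def test_full_rank_preserves_distances(self, training):
        p = fit_projection(training, k=12)
        feats = np.stack([project(s, p) for s in training])
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(feats), pdist(training), atol=1e-8)

    def test_projected_variances_non_increasing(self, training):
        p = fit_projection(training, k=8)
        feats = np.stack([project(s, p) for s in training])
        variances = feats.var(axis=0, ddof=1)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_projection_matches_sklearn_pca(self, training):
        """Independent cross-check against scikit-learn's PCA (components can
        differ by sign, so compare absolute loadings and variances)."""
        from sklearn.decomposition import PCA

        p = fit_projection(training, k=5)
        sk = PCA(n_components=5).fit(training)
        assert np.allclose(np.abs(p.eigenvectors), np.abs(sk.components_), atol=1e-8)
        assert np.allclose(p.eigenvalues, sk.explained_variance_, atol=1e-8)

    def test_eigenvector_adds_unit_feature(self, training):
        p = fit_projection(training, k=6)
        s = p.mean_vector + p.eigenvectors[2]
        expected = np.zeros(6)
        expected[2] = 1.0
        assert np.allclose(project(s, p), expected, atol=1e-9)

    def test_full_rank_reconstruction(self, training, rng):
        p = fit_projection(training, k=12)
        s = rng.normal(size=12)
        recon = p.eigenvectors.T @ project(s, p) + p.mean_vector
        assert np.allclose(recon, s, atol=1e-8)

    def test_order_invariance(self, training, rng):
        p1 = fit_projection(training, k=5)
        p2 = fit_projection(training[rng.permutation(len(training))], k=5)
        assert np.allclose(p1.eigenvectors, p2.eigenvectors, atol=1e-8)

    def test_k_out_of_range_rejected(self, training):
        with pytest.raises(ValueError):
            fit_projection(training, k=0)
        with pytest.raises(ValueError):
            fit_projection(training, k=13)


class TestNNClassify:
    def test_exact_match_wins(self, rng):
        X = rng.normal(size=(10, 4))
        labels = [f"c{i}" for i in range(10)]
        assert nn_classify(X[3], X, labels) == "c3"

    def test_separated_clusters(self, rng):
        a = rng.normal(size=(20, 3)) * 0.1
        b = rng.normal(size=(20, 3)) * 0.1 + 10.0
        X = np.vstack([a, b])
        labels = ["a"] * 20 + ["b"] * 20
        for q in rng.normal(size=(10, 3)) * 0.1:
            assert nn_classify(q, X, labels) == "a"
        for q in rng.normal(size=(10, 3)) * 0.1 + 10.0:
            assert nn_classify(q, X, labels) == "b"

    def test_single_item(self, rng):
        assert nn_classify(rng.normal(size=3), np.zeros((1, 3)), ["only"]) == "only"

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            nn_classify(np.zeros(3), np.empty((0, 3)), [])


def planar_trajectories(rng, n_per_class=8):
    """Two classes of trajectories confined to the y=0 great circle — an
    exactly 2-dimensional per-sample point cloud."""
    trajs, labels = [], []
    for cls, (lo, hi) in (("short", (0.1, 0.4)), ("long", (0.9, 1.4))):
        for _ in range(n_per_class):
            span = rng.uniform(lo, hi)
            t = np.linspace(0, span, 30)
            trajs.append(
                SpatialSequence(
                    vectors=np.column_stack([np.sin(t), np.zeros(30), np.cos(t)])
                )
            )
            labels.append(cls)
    return trajs, labels


class TestFullRankEquivalence:
    def test_full_rank_pca_equals_raw_nn(self, rng):
        """Projecting to all n·m components is an isometry, so 1-NN labels
        must match 1-NN on the raw flattened vectors."""
        trajs, labels = planar_trajectories(rng)
        L = 20
        vectors = np.stack([flatten(resample(t, L)) for t in trajs])
        p = fit_projection(vectors, k=3 * L)
        feats = np.stack([project(v, p) for v in vectors])
        for i in range(len(vectors)):
            mask = np.arange(len(vectors)) != i
            raw = nn_classify(vectors[i], vectors[mask],
                              [l for j, l in enumerate(labels) if j != i])
            proj = nn_classify(feats[i], feats[mask],
                               [l for j, l in enumerate(labels) if j != i])
            assert raw == proj


class TestTwoStage:
    def test_stage1_output_shape(self, rng):
        trajs, labels = planar_trajectories(rng)
        clf = TwoStagePCAClassifier(k2=5, resample_length=25).fit(trajs, labels)
        reduced = clf._reduce(trajs[0])
        assert reduced.shape == (25, 2)
        assert flatten(reduced).shape == (50,)

    def test_planar_data_stage1_lossless(self, rng):
        """On trajectories lying in a plane through the sphere, the 3->2
        reduction loses nothing: two-stage and single-stage predictions
        agree."""
        trajs, labels = planar_trajectories(rng)
        two = TwoStagePCAClassifier(k2=5, resample_length=25).fit(trajs, labels)
        one = PCAClassifier(k=5, resample_length=25).fit(trajs, labels)
        probes, probe_labels = planar_trajectories(np.random.default_rng(99), 4)
        for t, lbl in zip(probes, probe_labels):
            assert two.predict(t) == one.predict(t) == lbl

    def test_unfitted_predict_rejected(self, rng):
        with pytest.raises(ValueError):
            TwoStagePCAClassifier().predict(great_circle_arc(10))
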