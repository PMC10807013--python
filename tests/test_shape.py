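import logging

import numpy as np
import pytest

from earaam.shape import (EarShapeModel, PoseEstimationError, ShapeDimensionError,
                          SimilarityPose, build_shape_model, compute_weight_matrix,
                          landmarks_to_vector, procrustes_align, vector_to_landmarks)


def random_similarity(rng):
    return SimilarityPose(
        tx=rng.uniform(-50, 50), ty=rng.uniform(-50, 50),
        theta=rng.uniform(-np.pi / 3, np.pi / 3), s=rng.uniform(0.5, 2.0),
    )


class TestVectorization:
    def test_interleaved_ordering(self):
        pts = np.arange(182, dtype=float).reshape(91, 2)
        vec = landmarks_to_vector(pts)
        assert np.array_equal(vec[:4], [0.0, 1.0, 2.0, 3.0])

    def test_round_trip_is_identity(self, rng):
        pts = rng.normal(size=(91, 2))
        assert np.array_equal(vector_to_landmarks(landmarks_to_vector(pts)), pts)

    def test_zero_landmarks_give_zero_vector(self):
        assert np.array_equal(landmarks_to_vector(np.zeros((91, 2))), np.zeros(182))

    def test_wrong_count_raises(self):
        with pytest.raises(ShapeDimensionError):
            landmarks_to_vector(np.zeros((90, 2)))
        with pytest.raises(ShapeDimensionError):
            vector_to_landmarks(np.zeros(181))


class TestWeightMatrix:
    def test_identical_shapes_fall_back_to_uniform(self, rng, caplog):
        shape = rng.normal(size=10)
        with caplog.at_level(logging.WARNING):
            w = compute_weight_matrix([shape, shape, shape])
        assert np.allclose(w, 1.0)
        assert any("uniform" in r.message for r in caplog.records)

    def test_jittery_landmark_gets_lower_weight(self, rng):
        """Brute-force oracle on a 3-landmark toy set: landmarks 1-2 are
        fixed, landmark 3 jitters, so its distance variances are higher and
        its weight lower."""
        samples = []
        for _ in range(40):
            pts = np.array([[0.0, 0.0], [10.0, 0.0],
                            [5.0, 8.0 + rng.normal(0, 1.5)]])
            samples.append(pts.reshape(-1))
        w = compute_weight_matrix(samples)
        w_pts = w[::2]
        # independent oracle: per-landmark summed distance variance
        pts = np.asarray(samples).reshape(len(samples), 3, 2)
        d = np.linalg.norm(pts[:, :, None] - pts[:, None, :], axis=-1)
        sums = d.var(axis=0).sum(axis=1)
        expected = (1.0 / sums) / np.mean(1.0 / sums)
        assert np.allclose(w_pts, expected, atol=1e-12)
        assert w_pts[2] < w_pts[0]

    def test_translation_invariance(self, rng):
        shapes = [rng.normal(size=(5, 2)) for _ in range(6)]
        w1 = compute_weight_matrix([s.reshape(-1) for s in shapes])
        w2 = compute_weight_matrix([(s + [100.0, -30.0]).reshape(-1) for s in shapes])
        assert np.allclose(w1, w2)

    def test_to_point1_mode_uses_only_first_landmark(self, rng):
        samples = [rng.normal(size=(4, 2)).reshape(-1) for _ in range(8)]
        w = compute_weight_matrix(samples, mode="to_point1")
        pts = np.asarray(samples).reshape(8, 4, 2)
        d0 = np.linalg.norm(pts - pts[:, :1], axis=-1)  # distances to point 0
        var = d0.var(axis=0)
        raw = np.empty(4)
        raw[1:] = 1.0 / var[1:]
        raw[0] = raw[1:].mean()  # zero-variance landmark gets the mean weight
        assert np.allclose(w[::2], raw / raw.mean())


class TestProcrustes:
    def test_similarity_transforms_align_exactly(self, rng):
        base = rng.normal(size=(10, 2)) * 20
        shapes = [random_similarity(rng).apply(base).reshape(-1) for _ in range(6)]
        aligned, mean, poses = procrustes_align(shapes)
        for a in aligned:
            assert np.allclose(a, mean, atol=1e-6)

    def test_mean_is_a_fixed_point(self, rng):
        shapes = [(rng.normal(size=(8, 2)) * 10 + rng.normal(size=2) * 5).reshape(-1)
                  for _ in range(7)]
        aligned, mean, _ = procrustes_align(shapes)
        aligned2, mean2, _ = procrustes_align([a for a in aligned])
        assert np.sqrt(np.mean((mean2 - mean) ** 2)) < 1e-6

    def test_alignment_reduces_weighted_residual(self, rng):
        w = np.repeat(rng.uniform(0.5, 2.0, size=8), 2)
        shapes = [rng.normal(size=16) * 10 for _ in range(5)]
        aligned, mean, poses = procrustes_align(shapes, w)
        for orig, ali in zip(shapes, aligned):
            before = np.sum(w * (np.asarray(orig) - mean) ** 2)
            after = np.sum(w * (ali - mean) ** 2)
            assert after <= before + 1e-9

    def test_alignment_is_similarity_invariant(self, rng):
        shapes = [rng.normal(size=(6, 2)) * 15 for _ in range(5)]
        common = random_similarity(rng)
        a1, m1, _ = procrustes_align([s.reshape(-1) for s in shapes])
        a2, m2, _ = procrustes_align([common.apply(s).reshape(-1) for s in shapes])
        assert np.allclose(a1, a2, atol=1e-6)

    def test_degenerate_shape_raises(self):
        flat = np.zeros(10)
        with pytest.raises(PoseEstimationError):
            procrustes_align([flat, flat + 0.0])


class TestShapePCA:
    def test_rank_one_training_set_recovered(self, rng):
        base = rng.normal(size=20)
        v = rng.normal(size=20)
        v /= np.linalg.norm(v)
        shapes = [base + c * v for c in np.linspace(-2, 2, 9)]
        model = build_shape_model(shapes, variance_retained=1.0)
        assert model.n_components_ == 1
        dot = abs(model.components_[0] @ v)
        assert dot == pytest.approx(1.0, abs=1e-8)

    def test_full_basis_reconstructs_training_shapes(self, rng):
        shapes = [rng.normal(size=12) for _ in range(6)]
        model = build_shape_model(shapes, variance_retained=1.0)
        for s in shapes:
            w = model.components_ @ (s - model.mean_shape_)
            recon = model.mean_shape_ + model.components_.T @ w
            assert np.allclose(recon, s, atol=1e-6)

    def test_eigenvalue_sum_equals_covariance_trace(self, rng):
        X = np.asarray([rng.normal(size=10) for _ in range(7)])
        model = build_shape_model(X, variance_retained=1.0)
        centered = X - X.mean(axis=0)
        S = centered.T @ centered / len(X)
        assert np.sum(model.all_eigenvalues_) == pytest.approx(np.trace(S), abs=1e-8)

    def test_matches_brute_force_eigendecomposition(self, rng):
        X = np.asarray([rng.normal(size=(5, 2)).reshape(-1) for _ in range(8)])
        model = build_shape_model(X, variance_retained=1.0)
        centered = X - X.mean(axis=0)
        S = centered.T @ centered / len(X)
        eig = np.sort(np.linalg.eigvalsh(S))[::-1]
        k = len(model.all_eigenvalues_)
        assert np.allclose(model.all_eigenvalues_, eig[:k], atol=1e-8)

    def test_retained_variance_reaches_threshold(self, rng):
        X = [rng.normal(size=20) * np.linspace(3, 0.1, 20) for _ in range(15)]
        model = build_shape_model(X, variance_retained=0.9)
        assert model.retained_variance_fraction_ >= 0.9

    def test_basis_is_orthonormal(self, std_dataset):
        _, lms, _ = std_dataset
        model = EarShapeModel().fit(lms)
        G = model.components_ @ model.components_.T
        assert np.allclose(G, np.eye(model.n_components_), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues_) <= 1e-12)


def _orthonormalize(rows):
    basis = []
    for r in rows:
        v = r.astype(float).copy()
        for b in basis:
            v -= (v @ b) * b
        v /= np.linalg.norm(v)
        basis.append(v)
    return np.asarray(basis)


@pytest.fixture(scope="module")
def low_rank_model():
    """Hand-built 3-mode point-distribution model whose modes are orthogonal
    to the similarity gauge of the mean, so (pose, weights) is identifiable."""
    rng = np.random.default_rng(3)
    mean_pts = rng.normal(size=(12, 2)) * 25
    mean_pts -= mean_pts.mean(axis=0)
    mean = mean_pts.reshape(-1)
    sim = _orthonormalize([
        mean,
        np.column_stack([-mean_pts[:, 1], mean_pts[:, 0]]).reshape(-1),
        np.tile([1.0, 0.0], 12),
        np.tile([0.0, 1.0], 12),
    ])
    rows = _orthonormalize(list(sim) + list(rng.normal(size=(3, 24))))[4:]
    model = EarShapeModel(variance_retained=1.0)
    model.n_points_ = 12
    model.weight_matrix_ = np.ones(24)
    model.mean_shape_ = mean
    model.components_ = rows
    model.eigenvalues_ = np.array([20.0, 10.0, 4.0])
    model.all_eigenvalues_ = model.eigenvalues_
    model.n_components_ = 3
    model.aligned_shapes_ = None
    model.training_poses_ = None
    return model


class TestInstanceProjection:
    @pytest.fixture()
    def model(self, low_rank_model):
        return low_rank_model

    def test_zero_weights_identity_pose_gives_mean(self, model):
        pts = model.shape_instance()
        assert np.allclose(pts.reshape(-1), model.mean_shape_)

    def test_project_mean_gives_zero_weights(self, model):
        pose, w = model.project_shape(model.mean_shape_.reshape(-1, 2))
        assert np.allclose(w, 0.0, atol=1e-8)
        assert pose.s == pytest.approx(1.0, abs=1e-8)

    def test_project_recovers_instance_weights_and_pose(self, model, rng):
        w_true = 0.7 * np.sqrt(model.eigenvalues_[:3])
        pose = SimilarityPose(tx=12.0, ty=-7.0, theta=0.3, s=1.4)
        lm = model.shape_instance(w_true, pose)
        pose_hat, w_hat = model.project_shape(lm)
        assert np.allclose(w_hat[:3], w_true, atol=1e-6)
        assert np.allclose(w_hat[3:], 0.0, atol=1e-6)
        recon = model.shape_instance(w_hat, pose_hat)
        assert np.allclose(recon, lm, atol=1e-6)

    def test_residual_orthogonal_to_basis(self, model, rng):
        lm = model.shape_instance() + rng.normal(size=(12, 2))
        pose, w = model.project_shape(lm)
        aligned = pose.inverse().apply(lm).reshape(-1)
        residual = aligned - model.mean_shape_ - model.components_.T @ w
        assert np.allclose(model.components_ @ residual, 0.0, atol=1e-8)

    def test_doubled_scale_doubles_centroid_relative_coords(self, model):
        p1 = model.shape_instance(pose=SimilarityPose(s=1.0))
        p2 = model.shape_instance(pose=SimilarityPose(s=2.0))
        assert np.allclose(p2 - p2.mean(axis=0), 2 * (p1 - p1.mean(axis=0)), atol=1e-9)

    def test_degenerate_landmarks_raise(self, model):
        with pytest.raises(PoseEstimationError):
            model.project_shape(np.zeros((12, 2)))

    def test_too_many_weights_raise(self, model):
        with pytest.raises(ShapeDimensionError):
            model.shape_instance(np.zeros(model.n_components_ + 1))
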