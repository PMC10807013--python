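"""Statistical shape model: vectorization, weighted Procrustes alignment, PCA.

A shape is 91 landmarks, stored as the interleaved vector
(x1, y1, x2, y2, ..., x91, y91) of length 182.  Training shapes are aligned
to the evolving mean by the weighted similarity transform minimizing the
weighted sum of squared distances, where each landmark's weight is the
inverse of the summed across-sample variance of its distances to the other
landmarks (stable landmarks count more).  PCA of the aligned shapes yields
the mean shape and an orthonormal basis of deformation modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


class ShapeDimensionError(ValueError):
    """Landmark set or shape vector has the wrong size."""


class PoseEstimationError(ValueError):
    """Similarity pose cannot be estimated (degenerate landmark set)."""


class ConvergenceError(RuntimeError):
    """Iterative alignment failed to converge."""

    def __init__(self, message, residual_trace=None):
        super().__init__(message)
        self.residual_trace = residual_trace


@dataclass
class SimilarityPose:
    """Similarity transform p -> s * R(theta) @ p + (tx, ty)."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    s: float = 1.0

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError(f"scale must be positive, got {self.s}")

    @property
    def matrix(self) -> np.ndarray:
        c, d = self.s * np.cos(self.theta), self.s * np.sin(self.theta)
        return np.array([[c, -d], [d, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + np.array([self.tx, self.ty])

    def inverse(self) -> "SimilarityPose":
        inv_t = -np.array([self.tx, self.ty]) @ np.linalg.inv(self.matrix).T
        return SimilarityPose(tx=inv_t[0], ty=inv_t[1], theta=-self.theta, s=1.0 / self.s)

    @classmethod
    def from_affine(cls, a: float, b: float, tx: float, ty: float) -> "SimilarityPose":
        s = float(np.hypot(a, b))
        if s <= 0:
            raise PoseEstimationError("estimated similarity has zero scale")
        return cls(tx=float(tx), ty=float(ty), theta=float(np.arctan2(b, a)), s=s)


def landmarks_to_vector(lm, n_points: int = 91) -> np.ndarray:
    """Interleave an (N, 2) landmark array into the (2N,) shape vector."""
    pts = np.asarray(lm, dtype=float)
    if pts.shape != (n_points, 2):
        raise ShapeDimensionError(f"expected ({n_points}, 2) landmarks, got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ShapeDimensionError("landmark coordinates must be finite")
    return pts.reshape(-1)


def vector_to_landmarks(vec, n_points: int = 91) -> np.ndarray:
    """Inverse of :func:`landmarks_to_vector`."""
    v = np.asarray(vec, dtype=float).reshape(-1)
    if v.size != 2 * n_points:
        raise ShapeDimensionError(f"expected length {2 * n_points}, got {v.size}")
    return v.reshape(n_points, 2)


def compute_weight_matrix(training_shapes, mode: str = "all_pairs") -> np.ndarray:
    """Per-landmark alignment weights from across-sample distance variances.

    Returns the diagonal of the 2N-order weight matrix W (each landmark's
    weight repeated for its x and y entry), normalized to mean 1.

    ``mode='all_pairs'`` sums, over every other landmark i, the variance
    across training samples of the distance between landmark k and landmark i,
    and sets w_k to the inverse of the sum.  ``mode='to_point1'`` uses only
    the distance to landmark 0; ``mode='uniform'`` disables weighting.
    """
    shapes = np.asarray([np.asarray(s, dtype=float).reshape(-1) for s in training_shapes])
    if shapes.ndim != 2 or len(shapes) < 2:
        raise ValueError("need at least 2 training shapes")
    n_pts = shapes.shape[1] // 2
    pts = shapes.reshape(len(shapes), n_pts, 2)

    if mode == "uniform":
        return np.ones(2 * n_pts)
    if mode not in ("all_pairs", "to_point1"):
        raise ValueError(f"unknown weight mode {mode!r}")

    # distances[s, k, i] = |p_k - p_i| in sample s
    diff = pts[:, :, None, :] - pts[:, None, :, :]
    dists = np.linalg.norm(diff, axis=-1)
    var = dists.var(axis=0)  # (n_pts, n_pts), population variance across samples

    if mode == "all_pairs":
        sums = var.sum(axis=1)
    else:
        sums = var[:, 0]

    if np.all(sums <= 0):
        logger.warning("all inter-landmark distance variances are zero; using uniform weights")
        w = np.ones(n_pts)
    else:
        positive = sums > 0
        w = np.empty(n_pts)
        w[positive] = 1.0 / sums[positive]
        # landmarks with zero variance sum (e.g. point 0 in to_point1 mode)
        # get the mean of the defined weights rather than an infinite one
        w[~positive] = w[positive].mean()
    w = w / w.mean()
    return np.repeat(w, 2)


def _weighted_similarity_fit(src_pts, dst_pts, w) -> SimilarityPose:
    """Similarity T minimizing sum_k w_k |T(src_k) - dst_k|^2 (linear lstsq)."""
    src = np.asarray(src_pts, dtype=float)
    dst = np.asarray(dst_pts, dtype=float)
    n = len(src)
    sw = np.sqrt(np.asarray(w, dtype=float).reshape(-1)[: 2 * n : 2])
    centroid_size = np.linalg.norm(src - src.mean(axis=0))
    if centroid_size < 1e-12:
        raise PoseEstimationError("all source landmarks coincide; pose is undefined")
    A = np.zeros((2 * n, 4))
    A[0::2, 0] = src[:, 0] * sw
    A[0::2, 1] = -src[:, 1] * sw
    A[0::2, 2] = sw
    A[1::2, 0] = src[:, 1] * sw
    A[1::2, 1] = src[:, 0] * sw
    A[1::2, 3] = sw
    b = np.empty(2 * n)
    b[0::2] = dst[:, 0] * sw
    b[1::2] = dst[:, 1] * sw
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return SimilarityPose.from_affine(sol[0], sol[1], sol[2], sol[3])


def _normalize_mean(mean_vec: np.ndarray) -> np.ndarray:
    """Canonical mean: zero centroid, unit centroid size, fixed orientation.

    The orientation gauge (centroid-to-first-landmark direction at angle 0)
    pins the rotational freedom of the alignment, making the iteration a
    contraction and the result invariant to a common similarity transform of
    all inputs.
    """
    pts = mean_vec.reshape(-1, 2)
    pts = pts - pts.mean(axis=0)
    size = np.linalg.norm(pts)
    if size < 1e-12:
        raise PoseEstimationError("degenerate mean shape")
    pts = pts / size
    ref = pts[0]
    if np.linalg.norm(ref) < 1e-6:
        ref = pts[int(np.argmax(np.linalg.norm(pts, axis=1)))]
    ang = np.arctan2(ref[1], ref[0])
    c, s = np.cos(-ang), np.sin(-ang)
    pts = pts @ np.array([[c, s], [-s, c]])
    return pts.reshape(-1)


def procrustes_align(shapes, W=None, max_iter: int = 300, tol: float = 1e-7):
    """Iteratively align shapes to their evolving mean by weighted similarity fits.

    The mean is renormalized to zero centroid and unit centroid size each
    round.  Returns ``(aligned, mean, poses)`` where ``poses[i]`` maps the
    original shape i onto its aligned version.
    """
    X = np.asarray([np.asarray(s, dtype=float).reshape(-1) for s in shapes])
    if len(X) < 2:
        raise ValueError("need at least 2 shapes to align")
    n_pts = X.shape[1] // 2
    w = np.ones(2 * n_pts) if W is None else np.asarray(W, dtype=float).reshape(-1)

    mean = _normalize_mean(X[0].copy())
    aligned = X.copy()
    poses = [SimilarityPose() for _ in range(len(X))]
    trace = []
    for _ in range(max_iter):
        for i in range(len(X)):
            pose = _weighted_similarity_fit(X[i].reshape(-1, 2), mean.reshape(-1, 2), w)
            aligned[i] = pose.apply(X[i].reshape(-1, 2)).reshape(-1)
            poses[i] = pose
        new_mean = _normalize_mean(aligned.mean(axis=0))
        change = np.sqrt(np.mean((new_mean - mean) ** 2))
        trace.append(change)
        mean = new_mean
        if change < tol:
            return aligned, mean, poses
    raise ConvergenceError(
        f"Procrustes alignment did not converge in {max_iter} iterations", residual_trace=trace
    )


class EarShapeModel(BaseEstimator):
    """Point-distribution model of the 91 ear landmarks.

    Parameters
    ----------
    variance_retained : float, default 0.98
        Smallest number of PCA modes whose cumulative eigenvalue fraction
        reaches this value is kept (1.0 keeps every non-null mode).
    weight_mode : {'all_pairs', 'to_point1', 'uniform'}
        How the Procrustes landmark weights are computed.
    tangent_projection : bool, default False
        Optionally project aligned shapes into the tangent space of the mean.

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_shape_ : (2N,) mean of the aligned shapes (zero centroid, unit size).
    components_ : (n_components_, 2N) orthonormal deformation modes.
    eigenvalues_ : descending non-negative mode variances.
    weight_matrix_ : diagonal of the 2N-order Procrustes weight matrix.
    """

    def __init__(self, variance_retained=0.98, weight_mode="all_pairs",
                 tangent_projection=False, max_iter=300, tol=1e-7):
        self.variance_retained = variance_retained
        self.weight_mode = weight_mode
        self.tangent_projection = tangent_projection
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        """Fit from raw (unaligned) training shapes: (n, 2N) or list of (N, 2)."""
        X = np.asarray([np.asarray(s, dtype=float).reshape(-1) for s in X])
        if len(X) < 2:
            raise ValueError("need at least 2 training shapes")
        self.n_points_ = X.shape[1] // 2
        self.weight_matrix_ = compute_weight_matrix(X, mode=self.weight_mode)
        aligned, mean, poses = procrustes_align(
            X, self.weight_matrix_, max_iter=self.max_iter, tol=self.tol
        )
        # rotate the model frame from the alignment's canonical gauge to the
        # training data's mean orientation, so that placing the mean shape in
        # an image box yields an upright initialization
        angles = []
        for x in X:
            pose = _weighted_similarity_fit(
                mean.reshape(-1, 2), x.reshape(-1, 2), self.weight_matrix_
            )
            angles.append(pose.theta)
        theta = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
        R = SimilarityPose(theta=theta)
        mean = R.apply(mean.reshape(-1, 2)).reshape(-1)
        aligned = np.asarray([R.apply(a.reshape(-1, 2)).reshape(-1) for a in aligned])
        poses = [
            SimilarityPose(
                tx=float(R.matrix[0] @ [p.tx, p.ty]),
                ty=float(R.matrix[1] @ [p.tx, p.ty]),
                theta=p.theta + theta,
                s=p.s,
            )
            for p in poses
        ]
        if self.tangent_projection:
            dots = aligned @ mean
            aligned = aligned / dots[:, None]
        self.aligned_shapes_ = aligned
        self.training_poses_ = poses
        self._fit_pca(aligned, mean)
        return self

    def _fit_pca(self, aligned, mean):
        centered = aligned - mean
        # eigenvectors of S = (1/n) sum (a_i - mean)(a_i - mean)^T via SVD
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        eigvals = svals**2 / len(aligned)
        keep = eigvals > (1e-12 * max(eigvals.max(), 1e-300)
                          + 1e-15 * centered.shape[1])
        eigvals, vt = eigvals[keep], vt[keep]
        total = eigvals.sum()
        if total <= 0:
            n_comp = 0
        else:
            frac = np.cumsum(eigvals) / total
            n_comp = int(np.searchsorted(frac, self.variance_retained - 1e-12) + 1)
            n_comp = min(n_comp, len(eigvals))
        self.mean_shape_ = mean
        self.all_eigenvalues_ = eigvals
        self.eigenvalues_ = eigvals[:n_comp]
        self.components_ = vt[:n_comp]
        self.n_components_ = n_comp
        return self

    # -- synthesis / analysis ------------------------------------------------

    def shape_instance(self, weights=None, pose: SimilarityPose = None) -> np.ndarray:
        """Landmarks of mean + basis @ weights, similarity-transformed by pose."""
        vec = self.mean_shape_.copy()
        if weights is not None:
            w = np.asarray(weights, dtype=float).reshape(-1)
            if len(w) > self.n_components_:
                raise ShapeDimensionError(
                    f"{len(w)} weights but only {self.n_components_} modes retained"
                )
            big = np.abs(w) > 3 * np.sqrt(self.eigenvalues_[: len(w)]) + 1e-12
            if np.any(big):
                logger.info("shape weights beyond 3 sigma at modes %s", np.where(big)[0])
            vec = vec + self.components_[: len(w)].T @ w
        pts = vec.reshape(-1, 2)
        if pose is not None:
            pts = pose.apply(pts)
        return pts

    def project_shape(self, lm):
        """Optimal (pose, weights) so that shape_instance(weights, pose) ~= lm.

        Solved as one linear least-squares problem in the inverse direction,
        T^-1(lm) = mean + basis @ w, where the inverse-pose parameters and
        the weights all enter linearly; exact whenever lm is representable.
        """
        pts = np.asarray(lm, dtype=float).reshape(-1, 2)
        if pts.shape[0] != self.n_points_:
            raise ShapeDimensionError(f"expected {self.n_points_} landmarks, got {pts.shape[0]}")
        if np.linalg.norm(pts - pts.mean(axis=0)) < 1e-12:
            raise PoseEstimationError("all landmarks coincide; pose is undefined")
        n = self.n_points_
        sw = np.repeat(np.sqrt(self.weight_matrix_[::2]), 2)
        A = np.zeros((2 * n, 4 + self.n_components_))
        A[0::2, 0] = pts[:, 0]
        A[0::2, 1] = -pts[:, 1]
        A[0::2, 2] = 1.0
        A[1::2, 0] = pts[:, 1]
        A[1::2, 1] = pts[:, 0]
        A[1::2, 3] = 1.0
        A[:, 4:] = -self.components_.T
        Aw = A * sw[:, None]
        bw = self.mean_shape_ * sw
        U_, S_, Vt_ = np.linalg.svd(Aw, full_matrices=False)
        rank = S_ > S_[0] * 1e-10
        sol = Vt_[rank].T @ ((U_[:, rank].T @ bw) / S_[rank])
        null = Vt_[~rank].T
        if null.size:
            # overcomplete basis (shape modes overlap the similarity gauge):
            # among the residual minimizers take the one of minimal |weights|
            z, *_ = np.linalg.lstsq(null[4:], sol[4:], rcond=None)
            sol = sol - null @ z
        inv_pose = SimilarityPose.from_affine(*sol[:4])
        return inv_pose.inverse(), sol[4:]

    @property
    def retained_variance_fraction_(self) -> float:
        total = self.all_eigenvalues_.sum()
        return float(self.eigenvalues_.sum() / total) if total > 0 else 1.0


def build_shape_model(aligned_shapes, W=None, variance_retained: float = 0.98,
                      mean=None) -> EarShapeModel:
    """Build an :class:`EarShapeModel` directly from pre-aligned shapes."""
    X = np.asarray([np.asarray(s, dtype=float).reshape(-1) for s in aligned_shapes])
    if len(X) < 2:
        raise ValueError("need at least 2 aligned shapes")
    model = EarShapeModel(variance_retained=variance_retained)
    model.n_points_ = X.shape[1] // 2
    model.weight_matrix_ = (
        np.ones(X.shape[1]) if W is None else np.asarray(W, dtype=float).reshape(-1)
    )
    model.aligned_shapes_ = X
    model.training_poses_ = None
    model._fit_pca(X, X.mean(axis=0) if mean is None else np.asarray(mean, dtype=float))
    return model
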