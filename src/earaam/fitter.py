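"""Project-out inverse-compositional Lucas-Kanade fitting of the combined
shape + appearance model.

The landmark configuration is parameterized linearly in the appearance
reference frame as  s(p) = s_ref + Q p , where the columns of Q are the four
orthonormalized global-similarity basis vectors (scaling along the mean,
rotation of the mean, and the two translations; scale and translation are
exact in this linearization, rotation first-order) followed by the shape
modes orthogonalized against them.  Each iteration warps the image onto the
reference frame, normalizes the texture, computes the parameter update from
the precomputed appearance-projected steepest-descent images and Hessian,
and composes the inverse of the incremental warp with the current one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from earaam.appearance import (EarAppearanceModel, NormalizationError,
                               normalize_texture, to_grayscale)
from earaam.shape import SimilarityPose

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Fitting failed (e.g. the shape left the image); carries the last state."""

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class SingularHessianError(RuntimeError):
    """Gauss-Newton Hessian is singular even after regularization."""


@dataclass
class FitConfig:
    """Iteration budget and convergence tolerances of the Lucas-Kanade search."""

    max_iterations: int = 50
    tol_shape: float = 1e-4
    tol_residual: float = 1e-6
    max_halvings: int = 4
    verbose: bool = False

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tol_shape <= 0 or self.tol_residual <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FitResult:
    """Outcome of one fit: landmarks, pose/weights, residual trace, status."""

    landmarks: np.ndarray
    pose: SimilarityPose
    shape_weights: np.ndarray
    appearance_weights: np.ndarray
    residual_trace: list
    iterations: int
    converged: bool
    reason: str = ""
    params: np.ndarray = None

    @property
    def final_residual(self):
        return self.residual_trace[-1] if self.residual_trace else np.nan


def _orthonormal_rows(rows, against=None, tol=1e-10):
    """Gram-Schmidt of row vectors, optionally against an existing row basis."""
    basis = [] if against is None else [r for r in against]
    out = []
    for r in rows:
        v = r.astype(float).copy()
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n > tol:
            v /= n
            basis.append(v)
            out.append(v)
    return np.asarray(out)


def build_parameter_basis(shape_model, reference_shape):
    """Columns of Q: orthonormal similarity + shape modes in the reference frame.

    Returns ``(Q, n_similarity)`` with Q of shape (2N, 4 + n_modes).
    """
    ref = np.asarray(reference_shape, dtype=float).reshape(-1, 2)
    centered = ref - ref.mean(axis=0)
    n = len(ref)
    s_scale = centered.reshape(-1)
    s_rot = np.column_stack([-centered[:, 1], centered[:, 0]]).reshape(-1)
    s_tx = np.tile([1.0, 0.0], n)
    s_ty = np.tile([0.0, 1.0], n)
    sim = _orthonormal_rows(np.vstack([s_scale, s_rot, s_tx, s_ty]))
    shape_rows = _orthonormal_rows(shape_model.components_, against=sim)
    Q = np.vstack([sim, shape_rows]).T  # (2N, n_params)
    return Q, len(sim)


def _fill_outside_mask(frame, mask):
    """Replace pixels outside the mask with their nearest in-mask value."""
    if mask.all():
        return frame
    _, (iy, ix) = ndimage.distance_transform_edt(~mask, return_indices=True)
    return frame[iy, ix]


class AAMFitter:
    """Single-resolution inverse-compositional fitter for one model pair.

    Precomputes the steepest-descent images (gradients of the mean texture
    chained with the warp Jacobian), projects out the appearance modes, and
    factorizes the Gauss-Newton Hessian; per-image fitting then costs one
    warp + one matrix-vector product per iteration.
    """

    def __init__(self, shape_model, appearance_model: EarAppearanceModel):
        self.shape_model = shape_model
        self.appearance_model = appearance_model
        self.reference_shape = appearance_model.reference_shape_
        self.warper = appearance_model.warper_
        self.Q, self.n_similarity = build_parameter_basis(
            shape_model, self.reference_shape
        )
        self.ref_vec = self.reference_shape.reshape(-1)
        centered = self.reference_shape - self.reference_shape.mean(axis=0)
        self.param_scale = float(np.linalg.norm(centered))  # normalizes |dp|
        self._precompute()

    # -- precomputation ------------------------------------------------------

    def _precompute(self):
        warper = self.warper
        mean_img = warper.to_image(self.appearance_model.mean_texture_)
        mean_img = _fill_outside_mask(mean_img, warper.mask)
        gy, gx = np.gradient(mean_img)
        ix = gx[warper.mask]
        iy = gy[warper.mask]

        Qx = self.Q[0::2, :]  # (N, P)
        Qy = self.Q[1::2, :]
        tri_v = warper.mesh.triangles[warper.pixel_tri]  # (n_pix, 3)
        bary = warper.pixel_bary
        dxdp = np.einsum("nk,nkp->np", bary, Qx[tri_v])
        dydp = np.einsum("nk,nkp->np", bary, Qy[tri_v])
        J = ix[:, None] * dxdp + iy[:, None] * dydp

        U = self.appearance_model.components_  # (m, n_pix)
        self.J_aic = J - U.T @ (U @ J) if len(U) else J
        H = self.J_aic.T @ self.J_aic
        self.H = 0.5 * (H + H.T)
        self._factorize()

    def _factorize(self):
        H = self.H
        try:
            cond = np.linalg.cond(H)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            logger.warning("near-singular Hessian (cond=%.2e); regularizing", cond)
            H = H + (1e-8 * np.trace(H) / len(H) + 1e-12) * np.eye(len(H))
        try:
            self._chol = np.linalg.cholesky(H)
        except np.linalg.LinAlgError as exc:
            raise SingularHessianError("Hessian not positive definite") from exc

    def solve_update(self, residual) -> np.ndarray:
        rhs = self.J_aic.T @ residual
        z = np.linalg.solve(self._chol, rhs)
        return np.linalg.solve(self._chol.T, z)

    def project_out(self, texture) -> np.ndarray:
        """Apply the appearance-complement projector I - U_A U_A^T."""
        U = self.appearance_model.components_
        return texture - U.T @ (U @ texture) if len(U) else texture

    # -- parameterization ----------------------------------------------------

    def params_from_landmarks(self, landmarks) -> np.ndarray:
        vec = np.asarray(landmarks, dtype=float).reshape(-1)
        return self.Q.T @ (vec - self.ref_vec)

    def landmarks_from_params(self, p) -> np.ndarray:
        return (self.ref_vec + self.Q @ p).reshape(-1, 2)

    def compose_shape_update(self, p, delta_p) -> np.ndarray:
        """Inverse-compose an incremental update with the current warp.

        The inverse incremental warp is applied to the reference landmarks to
        first order (s_ref - Q dp), those points are mapped through the
        current piecewise-affine warp (barycentric extension outside the
        hull), and the result is re-projected onto the parameter basis.
        """
        delta_p = np.asarray(delta_p, dtype=float)
        if not np.any(delta_p):
            return np.asarray(p, dtype=float).copy()
        q_pts = (self.ref_vec - self.Q @ delta_p).reshape(-1, 2)
        current = self.landmarks_from_params(p)
        mapped = self._map_through_warp(q_pts, current)
        return self.Q.T @ (mapped.reshape(-1) - self.ref_vec)

    def _map_through_warp(self, points, current_landmarks) -> np.ndarray:
        """Piecewise-affine map (reference -> current) of arbitrary points.

        Each point uses the triangle whose barycentric coordinates are least
        negative, which extends the mesh affinely beyond its hull.
        """
        from earaam.appearance import barycentric_coords

        tris = self.warper.mesh.triangles
        ref = self.reference_shape
        pts = np.asarray(points, dtype=float)
        best_min = np.full(len(pts), -np.inf)
        best_bary = np.zeros((len(pts), 3))
        best_tri = np.zeros(len(pts), dtype=int)
        for t_idx, tri in enumerate(tris):
            a, b, g = barycentric_coords(pts, ref[tri[0]], ref[tri[1]], ref[tri[2]])
            m = np.minimum(np.minimum(a, b), g)
            better = m > best_min
            best_min[better] = m[better]
            best_tri[better] = t_idx
            best_bary[better, 0] = a[better]
            best_bary[better, 1] = b[better]
            best_bary[better, 2] = g[better]
        cur = np.asarray(current_landmarks, dtype=float).reshape(-1, 2)
        tri_pts = cur[tris[best_tri]]
        return np.einsum("nk,nkd->nd", best_bary, tri_pts)

    # -- fitting -------------------------------------------------------------

    def _residual(self, image, p):
        s = self.landmarks_from_params(p)
        tex = normalize_texture(self.warper.sample(image, s))
        r = tex - self.appearance_model.mean_texture_
        r_po = self.project_out(r)
        return s, tex, r, float(np.linalg.norm(r_po))

    def fit(self, image, init_landmarks, config: FitConfig = None) -> FitResult:
        """Run the inverse-compositional search from an initial landmark set."""
        config = config or FitConfig()
        img = to_grayscale(image)
        h, w = img.shape
        p = self.params_from_landmarks(init_landmarks)
        trace = []
        reason = "max_iter"
        converged = False
        best = None  # (residual, p, texture)
        it = 0
        try:
            for it in range(1, config.max_iterations + 1):
                s, tex, r, rnorm = self._residual(img, p)
                if not self._inside(s, h, w):
                    raise FitError("shape left the image during fitting",
                                   last_result=self._result(best or (rnorm, p, tex),
                                                            trace, it, False, "left_image"))
                if best is None or rnorm < best[0] - 1e-15:
                    best = (rnorm, p.copy(), tex)
                trace.append(rnorm)

                delta_p = self.solve_update(r)
                step = 1.0
                accepted = False
                for _ in range(config.max_halvings + 1):
                    p_try = self.compose_shape_update(p, step * delta_p)
                    s_try = self.landmarks_from_params(p_try)
                    if not self._inside(s_try, h, w):
                        step *= 0.5
                        continue
                    _, _, _, rnorm_try = self._residual(img, p_try)
                    if rnorm_try <= rnorm:
                        p = p_try
                        accepted = True
                        break
                    step *= 0.5
                # a fully rejected proposal means the accepted update is zero,
                # which is below any shape tolerance
                taken = step if accepted else 0.0
                update_norm = float(np.linalg.norm(taken * delta_p)) / self.param_scale
                if config.verbose:
                    logger.info("iter %d: residual %.6g, |dp| %.3g", it, rnorm, update_norm)
                if update_norm < config.tol_shape:
                    converged, reason = True, "tol_shape"
                    break
                if len(trace) >= 2 and abs(trace[-2] - trace[-1]) <= (
                    config.tol_residual * max(trace[-2], 1e-30)
                ):
                    converged, reason = True, "tol_residual"
                    break
                if not accepted:
                    reason = "stalled"
                    break
            else:
                it = config.max_iterations
            # the final parameters may beat every recorded iterate
            s, tex, r, rnorm = self._residual(img, p)
            if best is None or rnorm < best[0]:
                best = (rnorm, p.copy(), tex)
        except NormalizationError as exc:
            raise FitError(f"texture normalization failed: {exc}",
                           last_result=self._result(best, trace, it, False, "flat")) from exc
        return self._result(best, trace, it, converged, reason)

    @staticmethod
    def _inside(s, h, w, slack_frac=0.5):
        return (
            s[:, 0].min() > -slack_frac * w
            and s[:, 0].max() < (1 + slack_frac) * w
            and s[:, 1].min() > -slack_frac * h
            and s[:, 1].max() < (1 + slack_frac) * h
        )

    def _result(self, best, trace, iterations, converged, reason) -> FitResult:
        if best is None:
            raise FitError("no valid iterate was produced")
        rnorm, p, tex = best
        landmarks = self.landmarks_from_params(p)
        lam_prime = appearance_update(self.appearance_model, tex)
        pose, weights = self.shape_model.project_shape(landmarks)
        return FitResult(
            landmarks=landmarks,
            pose=pose,
            shape_weights=weights,
            appearance_weights=lam_prime,
            residual_trace=list(trace),
            iterations=iterations,
            converged=converged,
            reason=reason,
            params=p,
        )


def appearance_update(appearance_model, warped_normalized_texture, current=None):
    """Closed-form appearance weights: projection of (texture - mean) onto U_A."""
    return appearance_model.project_texture(warped_normalized_texture)


def precompute_ic(shape_model, appearance_model) -> AAMFitter:
    """Build the fitter with its steepest-descent images and Hessian."""
    return AAMFitter(shape_model, appearance_model)


def fit_aam(image, init_landmarks, shape_model, appearance_model,
            config: FitConfig = None) -> FitResult:
    """Functional wrapper: precompute + fit in one call."""
    return AAMFitter(shape_model, appearance_model).fit(image, init_landmarks, config)
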