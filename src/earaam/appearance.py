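"""Shape-free appearance model: reference triangulation, piecewise-affine
warping, texture normalization and texture PCA.

The mean shape is scaled into a small reference frame, triangulated
(Delaunay), and every training image is warped triangle-by-triangle onto that
frame: each reference pixel's barycentric coordinates in its triangle are
evaluated at the source image's corresponding triangle, and the image is
sampled bilinearly there.  The sampled gray vector is normalized to zero mean
and unit variance (removing global illumination gain/offset) before PCA.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay
from sklearn.base import BaseEstimator

LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateTriangleError(ValueError):
    """Triangle vertices are collinear."""


class WarpError(RuntimeError):
    """Piecewise-affine warp failed (too many degenerate source triangles)."""


class NormalizationError(ValueError):
    """Texture vector is constant; zero-variance normalization is undefined."""


class MeshError(ValueError):
    """Triangulation is empty or invalid."""


def to_grayscale(image) -> np.ndarray:
    """Float luminance image (0.299 R + 0.587 G + 0.114 B for color input)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ LUMA
    return img


class TriangleMesh:
    """Triangulation of the reference landmarks, with optional pruning.

    Triangles are stored as sorted vertex triples in lexicographic order, so
    point-location ties on shared edges resolve deterministically to the
    first matching triangle.
    """

    def __init__(self, triangles, pruned=()):
        tris = np.asarray(triangles, dtype=int)
        if tris.size == 0:
            raise MeshError("mesh has no triangles")
        tris = np.sort(tris, axis=1)
        order = np.lexsort((tris[:, 2], tris[:, 1], tris[:, 0]))
        self.triangles = tris[order]
        self.pruned = [tuple(sorted(t)) for t in pruned]

    def __len__(self):
        return len(self.triangles)


def triangulate_reference(reference_shape, exclusion_list=()) -> TriangleMesh:
    """Delaunay triangulation of the reference landmarks minus excluded triples."""
    pts = np.asarray(reference_shape, dtype=float).reshape(-1, 2)
    tri = Delaunay(pts)
    triples = [tuple(sorted(t)) for t in tri.simplices]
    excluded = {tuple(sorted(t)) for t in exclusion_list}
    kept = [t for t in triples if t not in excluded]
    if not kept:
        raise MeshError("exclusion list removed every triangle")
    # drop slivers that would make barycentric mapping ill-conditioned
    def _area(t):
        a, b, c = pts[list(t)]
        return 0.5 * abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))

    kept = [t for t in kept if _area(t) > 1e-9]
    if not kept:
        raise MeshError("all triangles are degenerate")
    removed = sorted(excluded | {t for t in triples if _area(t) <= 1e-9})
    return TriangleMesh(kept, pruned=removed)


def barycentric_coords(p, pi, pj, pk):
    """Barycentric coordinates (alpha, beta, gamma) of p in triangle (pi, pj, pk).

    Uses the closed-form signed-area ratios; gamma = 1 - alpha - beta.
    ``p`` may be a single point or an (n, 2) array.
    """
    p = np.asarray(p, dtype=float)
    (xi, yi), (xj, yj), (xk, yk) = (np.asarray(v, dtype=float) for v in (pi, pj, pk))
    denom_a = -(xi - xj) * (yk - yj) + (yi - yj) * (xk - xj)
    denom_b = -(xj - xk) * (yi - yk) + (yj - yk) * (xi - xk)
    if abs(denom_a) < 1e-12 or abs(denom_b) < 1e-12:
        raise DegenerateTriangleError("triangle vertices are collinear")
    x, y = p[..., 0], p[..., 1]
    alpha = (-(x - xj) * (yk - yj) + (y - yj) * (xk - xj)) / denom_a
    beta = (-(x - xk) * (yi - yk) + (y - yk) * (xi - xk)) / denom_b
    return alpha, beta, 1.0 - alpha - beta


class PiecewiseAffineWarper:
    """Precomputed piecewise-affine warp onto a fixed target shape.

    On construction, every pixel of the target frame inside the mesh is
    located in its triangle and its barycentric coordinates are stored; a
    warp from any source shape is then a barycentric combination of the
    source triangle vertices followed by bilinear sampling.
    """

    def __init__(self, target_shape, mesh: TriangleMesh, frame_shape=None):
        self.target_shape = np.asarray(target_shape, dtype=float).reshape(-1, 2)
        self.mesh = mesh
        if frame_shape is None:
            hi = np.ceil(self.target_shape.max(axis=0)).astype(int)
            frame_shape = (hi[1] + 2, hi[0] + 2)
        self.frame_shape = tuple(frame_shape)
        self._locate_pixels()

    def _locate_pixels(self):
        h, w = self.frame_shape
        xs, ys = np.meshgrid(np.arange(w), np.arange(h))
        pix = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        tri_of = np.full(len(pix), -1, dtype=int)
        bary = np.zeros((len(pix), 3))
        todo = np.arange(len(pix))
        tol = 1e-9
        for t_idx, tri in enumerate(self.mesh.triangles):
            if todo.size == 0:
                break
            a, b, g = barycentric_coords(
                pix[todo], *(self.target_shape[v] for v in tri)
            )
            inside = (a >= -tol) & (b >= -tol) & (g >= -tol)
            hit = todo[inside]
            tri_of[hit] = t_idx
            bary[hit, 0], bary[hit, 1], bary[hit, 2] = a[inside], b[inside], g[inside]
            todo = todo[~inside]
        self.mask_flat = tri_of >= 0
        self.mask = self.mask_flat.reshape(h, w)
        self.pixel_tri = tri_of[self.mask_flat]
        self.pixel_bary = bary[self.mask_flat]
        self.n_pixels = int(self.mask_flat.sum())
        if self.n_pixels == 0:
            raise MeshError("target mask is empty")

    def source_points(self, source_shape) -> np.ndarray:
        """Source-image coordinates for every masked target pixel."""
        src = np.asarray(source_shape, dtype=float).reshape(-1, 2)
        tri_pts = src[self.mesh.triangles[self.pixel_tri]]  # (n_pix, 3, 2)
        return np.einsum("nk,nkd->nd", self.pixel_bary, tri_pts)

    def degenerate_fraction(self, source_shape) -> float:
        src = np.asarray(source_shape, dtype=float).reshape(-1, 2)
        tris = self.mesh.triangles
        a, b, c = src[tris[:, 0]], src[tris[:, 1]], src[tris[:, 2]]
        areas = 0.5 * np.abs(
            (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
            - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
        )
        bad = areas < 1e-9
        if not bad.any():
            return 0.0
        return float(bad[self.pixel_tri].mean())

    def sample(self, image, source_shape) -> np.ndarray:
        """Texture vector: the image sampled at every masked target pixel."""
        img = to_grayscale(image)
        frac = self.degenerate_fraction(source_shape)
        if frac > 0.05:
            raise WarpError(f"{frac:.1%} of target pixels map through degenerate triangles")
        pts = self.source_points(source_shape)
        return ndimage.map_coordinates(
            img, [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
        )

    def to_image(self, texture, fill=0.0) -> np.ndarray:
        """Scatter a texture vector back into the 2-D reference frame."""
        out = np.full(self.frame_shape, fill, dtype=float)
        out[self.mask] = texture
        return out


def piecewise_affine_warp(image, source_shape, target_shape, mesh, frame_shape=None):
    """Warp *image* from *source_shape* onto *target_shape*.

    Returns ``(warped, mask)``: the warped image over the target frame (zero
    outside the mask) and the boolean mask of valid pixels.
    """
    warper = PiecewiseAffineWarper(target_shape, mesh, frame_shape=frame_shape)
    tex = warper.sample(image, source_shape)
    return warper.to_image(tex), warper.mask


def normalize_texture(g) -> np.ndarray:
    """Zero-mean, unit-variance (population) normalization of a gray vector."""
    g = np.asarray(g, dtype=float).reshape(-1)
    m = g.mean()
    sigma = g.std()  # population standard deviation
    if sigma < 1e-12:
        raise NormalizationError("constant texture has no unit-variance normalization")
    return (g - m) / sigma


class EarAppearanceModel(BaseEstimator):
    """PCA texture model in the shape-normalized reference frame.

    Parameters
    ----------
    variance_retained : float, default 0.98
        Cumulative eigenvalue fraction retained by the texture PCA.
    reference_extent : float, default 150
        Longest side, in pixels, of the mean shape's bounding box in the
        reference frame (sets texture dimensionality, ~10^4 pixels).
    exclusion_list : sequence of vertex triples
        Triangles pruned from the Delaunay triangulation.

    Attributes (after :meth:`fit`)
    ------------------------------
    reference_shape_ : (N, 2) mean landmarks in the reference frame.
    mesh_ : TriangleMesh over the reference landmarks.
    warper_ : precomputed :class:`PiecewiseAffineWarper` onto the reference.
    mean_texture_ : mean normalized texture.
    components_ : (n_components_, n_pixels) orthonormal texture modes.
    eigenvalues_ : descending texture-mode variances.
    """

    def __init__(self, variance_retained=0.98, reference_extent=150.0,
                 exclusion_list=(), margin=3.0):
        self.variance_retained = variance_retained
        self.reference_extent = reference_extent
        self.exclusion_list = exclusion_list
        self.margin = margin

    def reference_frame_from(self, mean_points) -> np.ndarray:
        """Scale/translate mean landmarks into the compact reference frame."""
        pts = np.asarray(mean_points, dtype=float).reshape(-1, 2)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        scale = self.reference_extent / max(hi - lo)
        return (pts - lo) * scale + self.margin

    def fit(self, images, landmark_sets, shape_model=None, y=None):
        """Fit from training images and their corresponding landmarks."""
        if len(images) != len(landmark_sets):
            raise ValueError("images and landmark_sets must pair up")
        if len(images) < 2:
            raise ValueError("need at least 2 training images")
        if shape_model is not None:
            mean_pts = shape_model.mean_shape_.reshape(-1, 2)
        else:
            from earaam.shape import procrustes_align

            _, mean, _ = procrustes_align(
                [np.asarray(l, dtype=float).reshape(-1) for l in landmark_sets]
            )
            mean_pts = mean.reshape(-1, 2)
        self.reference_shape_ = self.reference_frame_from(mean_pts)
        self.mesh_ = triangulate_reference(self.reference_shape_, self.exclusion_list)
        self.warper_ = PiecewiseAffineWarper(self.reference_shape_, self.mesh_)
        textures = np.array(
            [normalize_texture(self.warper_.sample(img, lm))
             for img, lm in zip(images, landmark_sets)]
        )
        self._fit_pca(textures)
        return self

    def _fit_pca(self, textures):
        self.mean_texture_ = textures.mean(axis=0)
        centered = textures - self.mean_texture_
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        eigvals = svals**2 / len(textures)
        # relative filter plus an absolute floor so that numerically
        # identical textures yield an empty basis
        keep = eigvals > (1e-12 * max(eigvals.max(), 1e-300)
                          + 1e-15 * textures.shape[1])
        eigvals, vt = eigvals[keep], vt[keep]
        total = eigvals.sum()
        if total <= 0:
            n_comp = 0
        else:
            frac = np.cumsum(eigvals) / total
            n_comp = int(np.searchsorted(frac, self.variance_retained - 1e-12) + 1)
            n_comp = min(n_comp, len(eigvals))
        self.all_eigenvalues_ = eigvals
        self.eigenvalues_ = eigvals[:n_comp]
        self.components_ = vt[:n_comp]
        self.n_components_ = n_comp
        return self

    def texture_instance(self, weights=None) -> np.ndarray:
        """Mean texture plus basis @ weights."""
        tex = self.mean_texture_.copy()
        if weights is not None:
            w = np.asarray(weights, dtype=float).reshape(-1)
            tex = tex + self.components_[: len(w)].T @ w
        return tex

    def project_texture(self, g) -> np.ndarray:
        """Basis coefficients of a (normalized) texture vector."""
        g = np.asarray(g, dtype=float).reshape(-1)
        return self.components_ @ (g - self.mean_texture_)

    def extract_texture(self, image, landmarks, normalized=True) -> np.ndarray:
        tex = self.warper_.sample(image, landmarks)
        return normalize_texture(tex) if normalized else tex


def build_appearance_model(images, landmark_sets, shape_model=None, mesh=None,
                           variance_retained=0.98, **kwargs) -> EarAppearanceModel:
    """Functional wrapper over :class:`EarAppearanceModel.fit`."""
    model = EarAppearanceModel(variance_retained=variance_retained, **kwargs)
    return model.fit(images, landmark_sets, shape_model=shape_model)
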