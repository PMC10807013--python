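import numpy as np
import pytest
from scipy import ndimage

from earaam.appearance import (DegenerateTriangleError, EarAppearanceModel,
                               MeshError, NormalizationError,
                               PiecewiseAffineWarper, barycentric_coords,
                               build_appearance_model, normalize_texture,
                               piecewise_affine_warp, triangulate_reference)


class TestTriangulation:
    def test_square_gives_two_triangles(self):
        square = [(0, 0), (10, 0), (10, 10), (0, 10)]
        mesh = triangulate_reference(square)
        assert len(mesh) == 2

    def test_exclusion_removes_exactly_one(self):
        square = [(0, 0), (10, 0), (10, 10), (0, 10)]
        full = triangulate_reference(square)
        pruned = triangulate_reference(square, exclusion_list=[tuple(full.triangles[0])])
        assert len(pruned) == len(full) - 1

    def test_excluding_everything_raises(self):
        square = [(0, 0), (10, 0), (10, 10), (0, 10)]
        full = triangulate_reference(square)
        with pytest.raises(MeshError):
            triangulate_reference(square, [tuple(t) for t in full.triangles])

    def test_interior_points_locate_in_exactly_one_triangle(self, rng):
        pts = rng.uniform(0, 50, size=(15, 2))
        mesh = triangulate_reference(pts)
        warper = PiecewiseAffineWarper(pts, mesh)
        # brute-force point location over all triangles, strict interior
        interior = warper.source_points(pts)
        for p in interior[rng.choice(len(interior), size=40)]:
            hits = 0
            for tri in mesh.triangles:
                a, b, g = barycentric_coords(p, *(pts[v] for v in tri))
                if min(a, b, g) > 1e-9:
                    hits += 1
            assert hits <= 1

    def test_template_triangulation_has_no_degenerate_triangle(self, template):
        mesh = triangulate_reference(template)
        for tri in mesh.triangles:
            a, b, c = template[tri]
            area = 0.5 * abs((b[0] - a[0]) * (c[1] - a[1])
                             - (c[0] - a[0]) * (b[1] - a[1]))
            assert area > 1e-6


class TestBarycentric:
    tri = (np.array([0.0, 0.0]), np.array([1.0, 0.0]), np.array([0.0, 1.0]))

    def test_vertex_gives_unit_coordinate(self):
        a, b, g = barycentric_coords(self.tri[0], *self.tri)
        assert (a, b, g) == pytest.approx((1.0, 0.0, 0.0), abs=1e-15)

    def test_centroid_gives_thirds(self):
        centroid = sum(self.tri) / 3.0
        coords = barycentric_coords(centroid, *self.tri)
        assert coords == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=1e-15)

    def test_matches_linear_solve_oracle(self, rng):
        for _ in range(50):
            tri = rng.uniform(-5, 5, size=(3, 2))
            e1, e2 = tri[1] - tri[0], tri[2] - tri[0]
            if abs(e1[0] * e2[1] - e1[1] * e2[0]) < 1e-3:
                continue
            p = rng.uniform(-2, 2, size=2)
            a, b, g = barycentric_coords(p, *tri)
            # oracle: solve the 2x2 linear system for (alpha, beta)
            M = np.column_stack([tri[0] - tri[2], tri[1] - tri[2]])
            ab = np.linalg.solve(M, p - tri[2])
            assert np.allclose([a, b, g], [ab[0], ab[1], 1 - ab.sum()], atol=1e-12)
            recon = a * tri[0] + b * tri[1] + g * tri[2]
            assert np.allclose(recon, p, atol=1e-9)

    def test_collinear_triangle_raises(self):
        with pytest.raises(DegenerateTriangleError):
            barycentric_coords([0.5, 0.5], [0, 0], [1, 1], [2, 2])


def _smooth_image(shape=(80, 80), seed=0):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.uniform(0, 255, size=shape), 6)
    return 255 * (img - img.min()) / (img.max() - img.min())


class TestPiecewiseAffineWarp:
    pts = np.array([(5.0, 5.0), (70.0, 8.0), (72.0, 70.0), (8.0, 68.0), (40.0, 35.0)])

    def test_identity_warp_reproduces_image_on_mask(self):
        img = _smooth_image()
        mesh = triangulate_reference(self.pts)
        warped, mask = piecewise_affine_warp(img, self.pts, self.pts,
                                             mesh, frame_shape=img.shape)
        assert np.allclose(warped[mask], img[mask], atol=1e-6)

    def test_similarity_warp_matches_closed_form_resampling(self):
        img = _smooth_image(seed=1)
        mesh = triangulate_reference(self.pts)
        c, s, t = 1.3 * np.cos(0.2), 1.3 * np.sin(0.2), np.array([4.0, 7.0])
        M = np.array([[c, -s], [s, c]])
        src = self.pts @ M.T + t
        warper = PiecewiseAffineWarper(self.pts, mesh, frame_shape=img.shape)
        sampled = warper.sample(img, src)
        # closed form: the same similarity applied to each target pixel
        xs, ys = np.where(warper.mask)[1], np.where(warper.mask)[0]
        mapped = np.column_stack([xs, ys]) @ M.T + t
        oracle = ndimage.map_coordinates(img, [mapped[:, 1], mapped[:, 0]],
                                         order=1, mode="nearest")
        assert np.max(np.abs(sampled - oracle)) < 1.0

    def test_round_trip_warp_small_error_on_smooth_image(self, rng):
        img = _smooth_image(seed=2)
        mesh = triangulate_reference(self.pts)
        other = self.pts + rng.uniform(-4, 4, size=self.pts.shape)
        a_to_b, mask = piecewise_affine_warp(img, self.pts, other, mesh,
                                             frame_shape=img.shape)
        back, mask2 = piecewise_affine_warp(a_to_b, other, self.pts, mesh,
                                            frame_shape=img.shape)
        inner = ndimage.binary_erosion(mask2, iterations=3)
        rms = np.sqrt(np.mean((back[inner] - img[inner]) ** 2))
        assert rms < 2.0

    def test_mask_is_independent_of_source_shape(self, rng):
        mesh = triangulate_reference(self.pts)
        warper = PiecewiseAffineWarper(self.pts, mesh, frame_shape=(80, 80))
        img = _smooth_image(seed=3)
        masks = []
        for _ in range(3):
            src = self.pts + rng.uniform(-6, 6, size=self.pts.shape)
            warper.sample(img, src)
            masks.append(warper.mask.copy())
        assert all(np.array_equal(masks[0], m) for m in masks)


class TestNormalizeTexture:
    def test_two_point_case(self):
        assert np.allclose(normalize_texture([0.0, 2.0]), [-1.0, 1.0])

    def test_idempotent(self, rng):
        g = rng.uniform(0, 255, size=50)
        once = normalize_texture(g)
        assert np.allclose(normalize_texture(once), once, atol=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        g = rng.uniform(0, 255, size=64)
        assert np.allclose(normalize_texture(3.2 * g + 17.0),
                           normalize_texture(g), atol=1e-9)

    def test_output_moments(self, rng):
        out = normalize_texture(rng.uniform(0, 255, size=200))
        assert abs(out.mean()) < 1e-9
        assert abs(out.var() - 1.0) < 1e-9

    def test_constant_vector_raises(self):
        with pytest.raises(NormalizationError):
            normalize_texture(np.full(10, 7.0))


class TestAppearanceModel:
    def test_identical_textures_give_zero_eigenvalues(self, std_dataset):
        imgs, lms, _ = std_dataset
        model = EarAppearanceModel(reference_extent=60).fit(
            [imgs[0]] * 3, [lms[0]] * 3
        )
        assert model.n_components_ == 0
        ref_tex = normalize_texture(model.warper_.sample(imgs[0], lms[0]))
        assert np.allclose(model.mean_texture_, ref_tex, atol=1e-9)

    def test_rank_one_texture_family_recovered(self, std_dataset, rng):
        imgs, lms, _ = std_dataset
        base = EarAppearanceModel(reference_extent=60).fit(imgs[:2], lms[:2])
        v = rng.normal(size=base.warper_.n_pixels)
        v /= np.linalg.norm(v)
        mean = base.mean_texture_
        textures = np.array([mean + c * v for c in np.linspace(-2, 2, 7)])
        model = EarAppearanceModel(reference_extent=60)
        model._fit_pca(textures)
        assert model.n_components_ == 1
        assert abs(model.components_[0] @ v) == pytest.approx(1.0, abs=1e-8)

    def test_training_texture_reconstruction_with_full_basis(self, std_dataset):
        imgs, lms, _ = std_dataset
        model = EarAppearanceModel(variance_retained=1.0,
                                   reference_extent=60).fit(imgs[:5], lms[:5])
        tex = model.extract_texture(imgs[2], lms[2])
        recon = model.texture_instance(model.project_texture(tex))
        assert np.allclose(recon, tex, atol=1e-6)

    def test_pca_matches_brute_force_on_tiny_textures(self, rng):
        textures = rng.normal(size=(8, 60))
        model = EarAppearanceModel(variance_retained=1.0)
        model._fit_pca(textures)
        centered = textures - textures.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(centered.T @ centered / 8))[::-1]
        k = len(model.all_eigenvalues_)
        assert np.allclose(model.all_eigenvalues_, eig[:k], atol=1e-8)

    def test_global_illumination_invariance(self, std_dataset):
        imgs, lms, _ = std_dataset
        model = EarAppearanceModel(reference_extent=80).fit(imgs[:3], lms[:3])
        t1 = model.extract_texture(imgs[0], lms[0])
        t2 = model.extract_texture(1.5 * imgs[0] + 20.0, lms[0])
        assert np.max(np.abs(t1 - t2)) < 1e-6

    def test_functional_wrapper_equivalent(self, std_dataset):
        imgs, lms, _ = std_dataset
        m = build_appearance_model(imgs[:3], lms[:3], reference_extent=60)
        assert m.n_components_ >= 1
        assert m.eigenvalues_[0] == m.all_eigenvalues_[0]
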