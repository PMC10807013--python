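import numpy as np
import pytest

from earaam.geometry import (EarlobeReconstruction, GeometryError, PolarFrame,
                             ReconstructionError, build_region_polygons,
                             densify_earlobe, divide_earlobe_nine,
                             extend_contour_endpoints, polar_interpolate,
                             reconstruct_earlobe, segment_regions,
                             _polygon_area)


def semicircle_contour(r=60.0, center=(100.0, 50.0), n=9):
    """Nine points on a semicircular lobe hanging below its base chord."""
    ang = np.linspace(np.pi, 2 * np.pi, n)
    return np.column_stack([center[0] + r * np.cos(ang),
                            center[1] + r * np.sin(-ang)])


class TestExtendContour:
    def test_collinear_points_extend_with_same_spacing(self):
        pts = np.column_stack([np.arange(9.0) * 2, np.zeros(9)])
        ext = extend_contour_endpoints(pts)
        assert np.allclose(ext[0], [-2.0, 0.0])
        assert np.allclose(ext[-1], [18.0, 0.0])

    def test_extension_length_equals_adjacent_segment(self, rng):
        pts = rng.uniform(0, 100, size=(9, 2))
        ext = extend_contour_endpoints(pts)
        assert np.linalg.norm(ext[0] - pts[0]) == pytest.approx(
            np.linalg.norm(pts[1] - pts[0]))
        assert np.linalg.norm(ext[-1] - pts[-1]) == pytest.approx(
            np.linalg.norm(pts[-1] - pts[-2]))

    def test_reversed_input_mirrors_construction(self, rng):
        pts = rng.uniform(0, 100, size=(9, 2))
        ext = extend_contour_endpoints(pts)
        ext_rev = extend_contour_endpoints(pts[::-1])
        assert np.allclose(ext_rev, ext[::-1])

    def test_coincident_points_raise(self):
        pts = np.zeros((9, 2))
        with pytest.raises(GeometryError):
            extend_contour_endpoints(pts)


class TestPolarInterpolate:
    def test_symmetric_pair_gives_midpoint_at_same_radius(self):
        frame = PolarFrame(origin=np.array([0.0, 0.0]))
        p1 = np.array([np.cos(0.3), np.sin(0.3)]) * 5
        p2 = np.array([np.cos(1.1), np.sin(1.1)]) * 5
        mid = polar_interpolate(p1, p2, frame, k_n=2)
        assert mid.shape == (1, 2)
        assert np.linalg.norm(mid[0]) == pytest.approx(5.0, abs=1e-9)
        assert np.arctan2(mid[0, 1], mid[0, 0]) == pytest.approx(0.7, abs=1e-9)

    def test_circular_arc_stays_on_circle(self):
        """Constant radius endpoints: every interpolant lies on the circle."""
        frame = PolarFrame(origin=np.array([3.0, -2.0]))
        r = 17.0
        p1 = frame.origin + r * np.array([np.cos(-0.4), np.sin(-0.4)])
        p2 = frame.origin + r * np.array([np.cos(0.9), np.sin(0.9)])
        pts = polar_interpolate(p1, p2, frame, k_n=4)
        assert len(pts) == 3
        radii = np.linalg.norm(pts - frame.origin, axis=1)
        assert np.allclose(radii, r, atol=1e-9)

    def test_radii_monotone_between_endpoints(self):
        frame = PolarFrame(origin=np.array([0.0, 0.0]))
        p1 = 4.0 * np.array([np.cos(0.2), np.sin(0.2)])
        p2 = 9.0 * np.array([np.cos(1.4), np.sin(1.4)])
        pts = polar_interpolate(p1, p2, frame, k_n=8)
        radii = np.linalg.norm(pts, axis=1)
        assert np.all(np.diff(np.concatenate([[4.0], radii, [9.0]])) > 0)

    def test_zero_angular_span_returns_empty(self):
        frame = PolarFrame(origin=np.array([0.0, 0.0]))
        pts = polar_interpolate([1.0, 0.0], [2.0, 0.0], frame, k_n=5)
        assert pts.shape == (0, 2)


class TestDensify:
    def test_circle_contour_reproduces_circle(self):
        contour = semicircle_contour()
        dense = densify_earlobe(contour, k_n=10)
        radii = np.linalg.norm(dense - np.array([100.0, 50.0]), axis=1)
        assert np.allclose(radii, 60.0, atol=1e-6)

    def test_input_points_preserved_and_count_correct(self):
        contour = semicircle_contour()
        k_n = 7
        dense = densify_earlobe(contour, k_n=k_n)
        assert len(dense) == 9 + 8 * (k_n - 1)
        for p in contour:
            assert np.min(np.linalg.norm(dense - p, axis=1)) < 1e-9


class TestReconstruct:
    def test_semicircular_lobe_depth_and_apex(self):
        contour = semicircle_contour(r=60.0)
        recon = reconstruct_earlobe(densify_earlobe(contour, k_n=20))
        assert recon.depth == pytest.approx(60.0, abs=1e-6)
        assert np.allclose(recon.apex, [100.0, 110.0], atol=1e-6)
        assert np.allclose(recon.reconstructed[0], contour[0])
        assert np.allclose(recon.reconstructed[8], contour[-1])

    def test_chord_points_satisfy_defining_constraints(self):
        contour = semicircle_contour(r=60.0)
        recon = reconstruct_earlobe(densify_earlobe(contour, k_n=20))
        p1, p9 = recon.base_chord
        base = (p9 - p1) / np.linalg.norm(p9 - p1)
        normal = np.array([-base[1], base[0]])
        h = recon.depth
        for p, frac in ((recon.reconstructed[1], 1 / 3), (recon.reconstructed[7], 1 / 3),
                        (recon.reconstructed[2], 2 / 3), (recon.reconstructed[6], 2 / 3)):
            d = abs((p - p1) @ normal)
            assert d == pytest.approx(frac * h, abs=1e-6)
        (p2, p8), (p3, p7) = recon.chords
        for a, b in (((p2 - p8), (p9 - p1)), ((p3 - p7), (p9 - p1))):
            cosang = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cosang == pytest.approx(1.0, abs=1e-9)

    def test_p4_bisects_arc_p3_to_p5(self):
        contour = semicircle_contour(r=60.0)
        recon = reconstruct_earlobe(densify_earlobe(contour, k_n=20))
        s = recon.stations
        assert s["P4"] - s["P3"] == pytest.approx(s["P5"] - s["P4"], abs=1e-6)
        assert s["P6"] - s["P5"] == pytest.approx(s["P7"] - s["P6"], abs=1e-6)

    def test_flat_contour_raises(self):
        flat = np.column_stack([np.linspace(0, 10, 12), np.zeros(12)])
        with pytest.raises(ReconstructionError):
            reconstruct_earlobe(flat)


@pytest.fixture(scope="module")
def recon():
    return reconstruct_earlobe(densify_earlobe(semicircle_contour(r=60.0), k_n=20))


class TestNineAreaDivision:

    def test_exactly_nine_subareas(self, recon):
        assert len(divide_earlobe_nine(recon)) == 9

    def test_tiling_conserves_area(self, recon):
        cells = divide_earlobe_nine(recon)
        total = sum(abs(_polygon_area(c)) for c in cells)
        lobe = np.vstack([recon.dense_contour])
        whole = abs(_polygon_area(lobe))
        assert abs(total - whole) / whole < 0.005

    def test_symmetric_lobe_has_mirror_equal_areas(self, recon):
        cells = [abs(_polygon_area(c)) for c in divide_earlobe_nine(recon)]
        for left, right in ((0, 2), (3, 5), (6, 8)):
            assert abs(cells[left] - cells[right]) / max(cells[left], cells[right]) < 0.01


class TestSimilarityEquivariance:
    def test_derived_points_transform_with_the_landmarks(self):
        from earaam.shape import SimilarityPose

        contour = semicircle_contour(r=60.0)
        pose = SimilarityPose(tx=30.0, ty=-12.0, theta=0.7, s=1.6)
        r1 = reconstruct_earlobe(densify_earlobe(contour, k_n=12))
        r2 = reconstruct_earlobe(densify_earlobe(pose.apply(contour), k_n=12))
        assert np.allclose(pose.apply(r1.reconstructed), r2.reconstructed, atol=1e-6)
        assert r2.depth == pytest.approx(1.6 * r1.depth, abs=1e-6)


class TestRegionsAndSegmentation:
    def test_all_nine_region_names_present(self, template, scheme, atlas):
        polys = build_region_polygons(template, scheme, atlas)
        assert set(polys) == set(atlas.regions)

    def test_regions_pairwise_interior_disjoint_on_template(self, template,
                                                            scheme, atlas):
        import shapely.geometry as sgeom

        polys = {k: sgeom.Polygon(v) for k, v in
                 build_region_polygons(template, scheme, atlas).items()}
        names = list(polys)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = polys[a].intersection(polys[b]).area
                assert inter < 0.01 * min(polys[a].area, polys[b].area), (a, b)

    def test_polygon_vertices_are_landmarks_or_derived_points(self, template,
                                                              scheme, atlas):
        from earaam.geometry import densify_earlobe, reconstruct_earlobe

        contour = template[list(scheme.earlobe_contour_indices)]
        derived = reconstruct_earlobe(densify_earlobe(contour)).reconstructed
        allowed = np.vstack([template, derived])
        polys = build_region_polygons(template, scheme, atlas)
        for poly in polys.values():
            for v in poly:
                assert np.min(np.linalg.norm(allowed - v, axis=1)) < 1e-9

    def test_segmentation_mask_and_overlay(self, template, scheme, atlas):
        import shapely.geometry as sgeom

        img = np.full((500, 500), 128.0)
        polys = build_region_polygons(template, scheme, atlas)
        mask, overlay = segment_regions(img, polys)
        assert overlay.shape == (500, 500, 3)
        labels, counts = np.unique(mask, return_counts=True)
        assert set(range(1, 10)).issubset(set(labels.tolist()))
        for label, (name, poly) in enumerate(polys.items(), start=1):
            shape = sgeom.Polygon(poly)
            probe = shape.buffer(-2)
            if probe.is_empty:
                probe = shape
            pt = probe.representative_point()
            assert mask[int(round(pt.y)), int(round(pt.x))] == label, name
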