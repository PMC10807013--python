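"""Post-fit ear geometry: earlobe contour densification, reconstruction of the
nine earlobe reference points, the nine-area earlobe division, region polygon
assembly, segmentation masks, and acupoint highlighting.

The earlobe pipeline follows the polar-interpolation construction: the raw
nine-point lobe contour is extended by one point at each end, the interior
angle bisectors at the two endpoints of every contour segment are intersected
to give a local polar origin, and interior points are interpolated with
uniformly spaced angles and radii linear in angle.  On the densified contour,
the apex P5 is the point farthest (depth h) from the base chord P1P9; chords
parallel to the base at distances 2h/3 and h/3 from P5 cut the contour at
(P2, P8) and (P3, P7); P4 and P6 bisect the arcs P3-P5 and P5-P7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Degenerate or inconsistent input geometry."""


class ReconstructionError(GeometryError):
    """Earlobe reference-point reconstruction failed."""


@dataclass
class PolarFrame:
    """Local polar coordinate system: origin and zero-angle direction."""

    origin: np.ndarray
    reference_axis: float = 0.0

    def to_polar(self, points):
        d = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.origin, dtype=float)
        r = np.linalg.norm(d, axis=1)
        theta = np.arctan2(d[:, 1], d[:, 0]) - self.reference_axis
        return r, theta

    def to_cartesian(self, r, theta):
        ang = np.asarray(theta, dtype=float) + self.reference_axis
        r = np.asarray(r, dtype=float)
        return np.asarray(self.origin, dtype=float) + np.column_stack(
            [r * np.cos(ang), r * np.sin(ang)]
        )


@dataclass
class EarlobeReconstruction:
    """Densified lobe contour and the reconstructed reference points P1..P9."""

    dense_contour: np.ndarray
    reconstructed: np.ndarray  # (9, 2): P1..P9
    depth: float
    stations: dict  # arclength station of each named point along dense_contour

    @property
    def base_chord(self):
        return self.reconstructed[0], self.reconstructed[8]

    @property
    def apex(self):
        return self.reconstructed[4]

    @property
    def chords(self):
        r = self.reconstructed
        return (r[1], r[7]), (r[2], r[6])


def _rotate(v, ang):
    c, s = np.cos(ang), np.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def extend_contour_endpoints(contour9) -> np.ndarray:
    """Prepend/append the reverse extensions of the first/last contour segments.

    The extension length equals the adjacent segment length and the extension
    direction repeats the turning angle at the neighbouring vertex, so a
    straight contour extends collinearly and a circular one stays on its
    circle (keeping the endpoint bisectors consistent with the interior ones).
    """
    pts = np.asarray(contour9, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise GeometryError("contour needs at least 3 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg < 1e-12):
        raise GeometryError("adjacent contour points coincide")

    def _extend(p0, p1, p2):
        # p0 is the end; repeat the turn observed at p1
        d_end = p0 - p1
        d_prev = p1 - p2
        turn = np.arctan2(d_end[1], d_end[0]) - np.arctan2(d_prev[1], d_prev[0])
        direction = _rotate(d_end / np.linalg.norm(d_end), turn)
        return p0 + np.linalg.norm(d_end) * direction

    p_start = _extend(pts[0], pts[1], pts[2])
    p_end = _extend(pts[-1], pts[-2], pts[-3])
    return np.vstack([p_start, pts, p_end])


def polar_interpolate(pn, pn1, frame: PolarFrame, k_n: int) -> np.ndarray:
    """The k_n - 1 interior points between pn and pn1 in the polar frame.

    Angles are uniformly spaced between the endpoint angles (shortest branch,
    |span| <= pi); radii vary linearly in angle between the endpoint radii.
    """
    if k_n < 1:
        raise GeometryError("k_n must be >= 1")
    pn = np.asarray(pn, dtype=float)
    pn1 = np.asarray(pn1, dtype=float)
    if np.allclose(pn, pn1):
        raise GeometryError("interpolation endpoints coincide")
    (r0, r1), (t0, t1) = frame.to_polar(np.vstack([pn, pn1]))
    if min(r0, r1) < 1e-12:
        raise GeometryError("endpoint at the polar origin")
    span = (t1 - t0 + np.pi) % (2 * np.pi) - np.pi  # branch with |span| <= pi
    if abs(span) < 1e-12:
        logger.warning("zero angular span between endpoints; no interior points")
        return np.empty((0, 2))
    k = np.arange(1, k_n)
    theta_k = t0 + (k / k_n) * span
    r_k = r0 + ((theta_k - t0) / span) * (r1 - r0)
    return frame.to_cartesian(r_k, theta_k)


def _interior_bisector(a, b, c) -> np.ndarray:
    """Unit direction of the interior bisector of angle a-b-c at vertex b."""
    u = (a - b) / np.linalg.norm(a - b)
    v = (c - b) / np.linalg.norm(c - b)
    d = u + v
    norm = np.linalg.norm(d)
    if norm < 1e-12:  # straight angle: bisector is the normal
        d = np.array([-u[1], u[0]])
        norm = 1.0
    return d / norm


def densify_earlobe(contour9, k_n: int = 10) -> np.ndarray:
    """Densified lobe contour: polar interpolation of every adjacent pair.

    For each pair (Pn, Pn+1) of the nine input points, the interior angle
    bisectors at Pn and Pn+1 (using the extended 11-point contour for the end
    segments) intersect at the local polar origin Oi; k_n - 1 points are
    interpolated between the pair.  Input points are retained, so the output
    has 9 + 8 (k_n - 1) points when no segment falls back to linear
    interpolation (near-parallel bisectors).
    """
    pts = np.asarray(contour9, dtype=float).reshape(-1, 2)
    ext = extend_contour_endpoints(pts)  # indices 0..10; original n -> ext[n+1]
    out = [pts[0]]
    for n in range(len(pts) - 1):
        b1 = _interior_bisector(ext[n], ext[n + 1], ext[n + 2])
        b2 = _interior_bisector(ext[n + 1], ext[n + 2], ext[n + 3])
        p1, p2 = ext[n + 1], ext[n + 2]
        cross = b1[0] * b2[1] - b1[1] * b2[0]
        interior = None
        if abs(cross) > 1e-9:
            t = ((p2[0] - p1[0]) * b2[1] - (p2[1] - p1[1]) * b2[0]) / cross
            origin = p1 + t * b1
            if min(np.linalg.norm(p1 - origin), np.linalg.norm(p2 - origin)) > 1e-9:
                try:
                    interior = polar_interpolate(p1, p2, PolarFrame(origin), k_n)
                except GeometryError:
                    interior = None
        if interior is None:
            logger.info("segment %d: bisectors near-parallel, linear fallback", n)
            s = np.arange(1, k_n)[:, None] / k_n
            interior = p1 + s * (p2 - p1)
        out.extend(interior)
        out.append(p2)
    return np.asarray(out)


def _polyline_stations(contour) -> np.ndarray:
    seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_station(contour, stations, s) -> np.ndarray:
    s = float(np.clip(s, stations[0], stations[-1]))
    i = int(np.searchsorted(stations, s, side="right") - 1)
    i = min(i, len(contour) - 2)
    span = stations[i + 1] - stations[i]
    t = 0.0 if span <= 0 else (s - stations[i]) / span
    return contour[i] + t * (contour[i + 1] - contour[i])


def _level_crossings(d, stations):
    """Stations where the signed-depth polyline crosses zero, in order."""
    hits = []
    for i in range(len(d) - 1):
        if d[i] == 0.0:
            hits.append(stations[i])
        elif (d[i] < 0) != (d[i + 1] < 0):
            t = d[i] / (d[i] - d[i + 1])
            hits.append(stations[i] + t * (stations[i + 1] - stations[i]))
    if len(d) and d[-1] == 0.0:
        hits.append(stations[-1])
    return hits


def reconstruct_earlobe(dense_contour) -> EarlobeReconstruction:
    """Reconstruct P1..P9 from a densified lobe contour.

    P1 and P9 are the contour endpoints; P5 the point of maximal perpendicular
    depth h from the base chord P1P9; P2/P8 and P3/P7 the contour crossings of
    the chords parallel to the base at depths h/3 and 2h/3 (distances 2h/3 and
    h/3 from P5) flanking the apex; P4 and P6 the arclength midpoints of the
    contour arcs P3-P5 and P5-P7.
    """
    c = np.asarray(dense_contour, dtype=float).reshape(-1, 2)
    if len(c) < 9:
        raise ReconstructionError("dense contour needs at least 9 points")
    p1, p9 = c[0], c[-1]
    base = p9 - p1
    base_len = np.linalg.norm(base)
    if base_len < 1e-12:
        raise ReconstructionError("base chord P1P9 is degenerate")
    normal = np.array([-base[1], base[0]]) / base_len
    depth_all = (c - p1) @ normal
    if np.abs(depth_all).max() < 1e-12:
        raise ReconstructionError("contour is collinear with the base chord")
    if depth_all.sum() < 0:  # orient the normal toward the lobe side
        normal = -normal
        depth_all = -depth_all
    stations = _polyline_stations(c)
    i5 = int(np.argmax(depth_all))  # first maximal point along the contour
    h = float(depth_all[i5])
    if h <= 0:
        raise ReconstructionError("lobe depth is non-positive")
    p5 = c[i5]
    s5 = stations[i5]

    named = {}
    for frac, (name_lo, name_hi) in (((1.0 / 3.0), ("P2", "P8")), ((2.0 / 3.0), ("P3", "P7"))):
        hits = _level_crossings(depth_all - frac * h, stations)
        before = [s for s in hits if s < s5]
        after = [s for s in hits if s > s5]
        if not before or not after:
            raise ReconstructionError(
                f"chord {name_lo}{name_hi} at depth {frac:.3f} h does not cross the "
                "contour on both sides of the apex"
            )
        named[name_lo] = max(before)  # the crossings flanking P5
        named[name_hi] = min(after)
    named["P4"] = 0.5 * (named["P3"] + s5)
    named["P6"] = 0.5 * (s5 + named["P7"])
    named["P1"], named["P5"], named["P9"] = stations[0], s5, stations[-1]

    recon = np.vstack(
        [_point_at_station(c, stations, named[f"P{k}"]) for k in range(1, 10)]
    )
    recon[0], recon[8], recon[4] = p1, p9, p5  # exact endpoints and apex
    return EarlobeReconstruction(
        dense_contour=c, reconstructed=recon, depth=h, stations=named
    )


def _arc(contour, stations_axis, s_a, s_b, pt_a, pt_b):
    """Polyline from station s_a to s_b (either direction), exact endpoints."""
    if s_a <= s_b:
        inner = contour[(stations_axis > s_a + 1e-9) & (stations_axis < s_b - 1e-9)]
    else:
        inner = contour[(stations_axis < s_a - 1e-9) & (stations_axis > s_b + 1e-9)][::-1]
    return np.vstack([pt_a, inner, pt_b]) if len(inner) else np.vstack([pt_a, pt_b])


def _ray_polyline_hit(origin, direction, contour, stations_axis, s_min):
    """First intersection of a ray with the contour at station > s_min."""
    best = None
    d = direction / np.linalg.norm(direction)
    for i in range(len(contour) - 1):
        if stations_axis[i + 1] <= s_min:
            continue
        a, b = contour[i], contour[i + 1]
        e = b - a
        det = e[0] * d[1] - d[0] * e[1]  # t*d - u*e = a - origin (Cramer)
        if abs(det) < 1e-12:
            continue
        w = a - origin
        t = (e[0] * w[1] - e[1] * w[0]) / det
        u = (d[0] * w[1] - d[1] * w[0]) / det
        if t > 1e-9 and -1e-9 <= u <= 1 + 1e-9:
            s_hit = stations_axis[i] + np.clip(u, 0, 1) * (
                stations_axis[i + 1] - stations_axis[i]
            )
            if best is None or t < best[0]:
                best = (t, origin + t * d, s_hit)
    if best is None:
        raise ReconstructionError("division ray does not meet the lobe contour")
    return best[1], best[2]


def divide_earlobe_nine(recon: EarlobeReconstruction):
    """The nine labelled earlobe sub-areas (3 x 3, standard reading order).

    The chords P1P9, P2P8 and P3P7 are each split at their third-points;
    corresponding third-points are connected across chords, the connections
    continued below P3P7 until they meet the lobe contour, and the contour
    closes the outer boundaries.  Returns a list of nine (m, 2) closed
    polygons ordered row-major from the base chord down to the apex.
    """
    c = recon.dense_contour
    st = _polyline_stations(c)
    P = {f"P{k}": recon.reconstructed[k - 1] for k in range(1, 10)}
    S = recon.stations

    def thirds(a, b):
        return a + (b - a) / 3.0, a + 2.0 * (b - a) / 3.0

    A1, A2 = thirds(P["P1"], P["P9"])
    B1, B2 = thirds(P["P2"], P["P8"])
    C1, C2 = thirds(P["P3"], P["P7"])
    D1, sD1 = _ray_polyline_hit(C1, C1 - B1, c, st, S["P3"])
    D2, sD2 = _ray_polyline_hit(C2, C2 - B2, c, st, S["P3"])
    if not (S["P3"] < sD1 < sD2 < S["P7"]):
        raise GeometryError("bottom-row division rays cross or leave the apex arc")

    def arc(na, nb, pa, pb):
        return _arc(c, st, na, nb, pa, pb)

    cells = [
        np.vstack([P["P1"], A1, B1, P["P2"], arc(S["P2"], S["P1"], P["P2"], P["P1"])[1:-1]]),
        np.vstack([A1, A2, B2, B1]),
        np.vstack([A2, P["P9"], arc(S["P9"], S["P8"], P["P9"], P["P8"])[1:-1], P["P8"], B2]),
        np.vstack([P["P2"], B1, C1, P["P3"], arc(S["P3"], S["P2"], P["P3"], P["P2"])[1:-1]]),
        np.vstack([B1, B2, C2, C1]),
        np.vstack([B2, P["P8"], arc(S["P8"], S["P7"], P["P8"], P["P7"])[1:-1], P["P7"], C2]),
        np.vstack([P["P3"], C1, arc(sD1, S["P3"], D1, P["P3"])[:-1]]),
        np.vstack([C1, C2, arc(sD2, sD1, D2, D1)]),
        np.vstack([C2, P["P7"], arc(S["P7"], sD2, P["P7"], D2)[1:-1], D2]),
    ]
    for i, poly in enumerate(cells):
        if abs(_polygon_area(poly)) < 1e-9:
            raise GeometryError(f"sub-area {i + 1} is degenerate")
    return cells


def _polygon_area(poly) -> float:
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def build_region_polygons(landmarks, scheme, atlas, return_flags: bool = False):
    """Assemble the nine named region polygons from fitted landmarks.

    Atlas vertices are landmark indices or ``"Pk"`` tokens resolved against
    the earlobe reconstruction.  Self-intersecting polygons fall back to
    their convex hull with a warning (flag reported when requested).
    """
    import shapely.geometry as sgeom

    lm = np.asarray(landmarks, dtype=float).reshape(-1, 2)
    derived = None
    polys, flags = {}, {}
    for name, verts in atlas.regions.items():
        coords = []
        for v in verts:
            if isinstance(v, str):
                if derived is None:
                    contour9 = lm[list(scheme.earlobe_contour_indices)]
                    derived = reconstruct_earlobe(densify_earlobe(contour9)).reconstructed
                coords.append(derived[int(v[1:]) - 1])
            else:
                coords.append(lm[int(v)])
        poly = np.asarray(coords, dtype=float)
        flags[name] = False
        if not sgeom.Polygon(poly).is_valid:
            logger.warning("region %r polygon self-intersects; using convex hull", name)
            hull = sgeom.MultiPoint([tuple(p) for p in poly]).convex_hull
            poly = np.asarray(hull.exterior.coords[:-1], dtype=float)
            flags[name] = True
        polys[name] = poly
    return (polys, flags) if return_flags else polys


def segment_regions(image, polygons):
    """Rasterize region polygons into a label mask and a color overlay.

    Returns ``(mask, overlay)``: an integer mask (0 background, 1..9 regions
    in listed order, first-listed wins on overlap) and an RGB uint8 overlay
    with filled regions and drawn boundaries.
    """
    from skimage.draw import polygon as draw_polygon
    from skimage.draw import polygon_perimeter

    img = np.asarray(image)
    if img.ndim == 3:
        gray = img[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
    else:
        gray = img.astype(float)
    h, w = gray.shape
    mask = np.zeros((h, w), dtype=np.uint8)
    colors = _region_colors(len(polygons))
    overlay = np.repeat(np.clip(gray, 0, 255).astype(np.uint8)[..., None], 3, axis=2)
    for label, (name, poly) in enumerate(polygons.items(), start=1):
        poly = np.asarray(poly, dtype=float)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        new = mask[rr, cc] == 0
        mask[rr[new], cc[new]] = label
        color = np.asarray(colors[label - 1], dtype=float)
        overlay[rr[new], cc[new]] = (
            0.55 * overlay[rr[new], cc[new]] + 0.45 * color
        ).astype(np.uint8)
        pr, pc = polygon_perimeter(poly[:, 1], poly[:, 0], shape=(h, w), clip=True)
        overlay[pr, pc] = color
    return mask, overlay


def _region_colors(n):
    import colorsys

    return [
        tuple(int(255 * v) for v in colorsys.hsv_to_rgb(i / max(n, 1), 0.85, 1.0))
        for i in range(n)
    ]


def highlight_acupoint(image, name, landmarks, atlas, registry=None, scheme=None):
    """Overlay with the named acupoint's area filled or its point marked."""
    from skimage.draw import disk as draw_disk
    from skimage.draw import polygon as draw_polygon
    from skimage.draw import polygon_perimeter

    from earaam.scheme import lookup_acupoint

    kind, geom = lookup_acupoint(name, atlas, landmarks, registry=registry, scheme=scheme)
    img = np.asarray(image)
    if img.ndim == 3:
        gray = img[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
    else:
        gray = img.astype(float)
    overlay = np.repeat(np.clip(gray, 0, 255).astype(np.uint8)[..., None], 3, axis=2)
    color = np.array([255, 40, 40], dtype=float)
    h, w = gray.shape
    if kind == "area":
        poly = np.asarray(geom, dtype=float)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        overlay[rr, cc] = (0.45 * overlay[rr, cc] + 0.55 * color).astype(np.uint8)
        pr, pc = polygon_perimeter(poly[:, 1], poly[:, 0], shape=(h, w), clip=True)
        overlay[pr, pc] = color.astype(np.uint8)
    else:
        x, y = geom
        rr, cc = draw_disk((y, x), 4.0, shape=(h, w))
        overlay[rr, cc] = color.astype(np.uint8)
    return kind, geom, overlay
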