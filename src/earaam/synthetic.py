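"""Procedural ear-like images with exact ground-truth 91-point landmarks.

The canonical template lays the 91 landmarks out on an egg-shaped outer
contour (helix rim), concentric inner ridge curves (inner helix edge,
antihelix), a conchal ellipse, tragus/antitragus points and a nine-point
earlobe contour, matching the shipped landmark scheme's index semantics.
Samples deform the template by a few fixed smooth low-frequency fields plus
similarity jitter, and images are rendered as region-wise flat shading with
ridge darkening, Gaussian-blurred boundaries, and configurable illumination
(gain/offset/linear gradient) and additive noise.

The "standard" profile emulates uniformly lit clinical captures at
500 x 500 pixels; the "degraded" profile emulates hand-held phone photos via
an illumination gradient of up to +-30% across the frame, gain/offset jitter
and additive Gaussian noise (sigma up to 8 gray levels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from earaam import scheme as scheme_mod
from earaam.geometry import build_region_polygons

# template frame constants (pixels, 500 x 500 canvas)
_CX, _CY = 250.0, 245.0
_A, _B = 105.0, 175.0
_LOBE_HALF_SPAN = 0.55  # lobe arc half-width in outline parameter t

#: per-region base intensity of the rendered shading (gray levels)
REGION_INTENSITY = {
    "helix": 205.0,
    "antihelix": 172.0,
    "cymba conchae": 120.0,
    "cavum conchae": 108.0,
    "fossae helicis": 92.0,
    "fossae triangularis auriculae": 104.0,
    "tragus": 188.0,
    "antitragus": 178.0,
    "earlobe": 215.0,
}
_SKIN, _BACKGROUND = 158.0, 45.0


def _outline(t):
    t = np.asarray(t, dtype=float)
    w = _A * (1.0 - 0.35 * (1.0 - np.cos(t)) / 2.0)
    return np.column_stack([_CX + w * np.sin(t), _CY - _B * np.cos(t)])


def _scaled_outline(t, scale):
    pts = _outline(t)
    return np.array([_CX, _CY]) + np.atleast_1d(scale)[:, None] * (
        pts - np.array([_CX, _CY])
    )


def generate_template() -> np.ndarray:
    """The canonical 91-point synthetic ear, consistent with the shipped scheme."""
    pts = np.zeros((91, 2))
    lo, hi = np.pi - _LOBE_HALF_SPAN, np.pi + _LOBE_HALF_SPAN
    # 0-35: outer helix rim, clockwise from the front lower attachment
    pts[0:36] = _outline(np.linspace(hi + 0.07, 2 * np.pi + lo - 0.07, 36))
    # 36-55: inner helix edge (narrower groove along the front edge)
    t_inner = np.linspace(np.pi + 0.75, 3 * np.pi - 0.75, 20)
    s_inner = 0.80 + 0.07 * np.maximum(0.0, -np.sin(t_inner))
    pts[36:56] = _scaled_outline(t_inner, s_inner)
    # 56-67: antihelix ridge
    t_anti = np.linspace(2 * np.pi - 0.4, 3 * np.pi - 0.9, 12)
    pts[56:68] = _scaled_outline(t_anti, np.full(12, 0.56))
    # 68-75: conchal rim (ellipse, clockwise from the top)
    phi = np.linspace(0, 2 * np.pi, 9)[:-1]
    pts[68:76] = np.column_stack([244.0 + 44.0 * np.sin(phi), 265.0 - 62.0 * np.cos(phi)])
    # 76-79: tragus; 80-81: antitragus
    pts[76:80] = [[178.0, 238.0], [193.0, 247.0], [195.0, 272.0], [180.0, 280.0]]
    pts[80:82] = [[222.0, 352.0], [256.0, 344.0]]
    # 82-90: earlobe contour, rear junction to front junction
    pts[82:91] = _outline(np.linspace(2 * np.pi + lo, 2 * np.pi + hi, 9))
    return pts


def _deformation_modes(template: np.ndarray) -> np.ndarray:
    """Fixed smooth low-frequency fields, each normalized to 1 px RMS."""
    u = (template[:, 0] - _CX) / _A
    v = (template[:, 1] - _CY) / _B
    zeros = np.zeros_like(u)
    fields = [
        np.column_stack([u, zeros]),                       # width stretch
        np.column_stack([0.5 * u * np.maximum(v, 0) ** 2,
                         np.maximum(v, 0) ** 2]),          # lobe growth
        np.column_stack([v, zeros]),                       # vertical shear
        np.column_stack([u * (1 - v**2), -v * (1 - u**2)]),  # bulge/twist
    ]
    modes = []
    for f in fields:
        rms = np.sqrt(np.mean(np.sum(f**2, axis=1)))
        modes.append(f / rms)
    return np.asarray(modes)  # (n_modes, 91, 2)


@dataclass
class SynthesisParams:
    """Study conditions of the synthetic generator.

    ``shape_jitter`` holds the per-mode standard deviations (px RMS) of the
    smooth template deformations; ``illumination`` the gain/offset/gradient
    jitter half-ranges; ``noise_sigma`` the additive noise level range
    (8-bit gray levels).  The seed is mandatory for reproducibility.
    """

    seed: int
    image_size: tuple = (500, 500)
    shape_jitter: tuple = (3.0, 2.5, 2.0, 1.5)
    scale_jitter: float = 0.08
    rotation_jitter: float = 0.10  # radians, half-range
    translation_jitter: float = 12.0
    gain_jitter: float = 0.0
    offset_jitter: float = 0.0
    gradient_amplitude: float = 0.0
    noise_sigma: tuple = (1.0, 2.0)
    blur_sigma: float = 3.0
    profile: str = "standard"

    def __post_init__(self):
        if min(self.image_size) < 128:
            raise ValueError("image_size must be at least 128 pixels")
        if min(self.noise_sigma) < 0:
            raise ValueError("noise_sigma must be non-negative")

    @classmethod
    def standard(cls, seed: int) -> "SynthesisParams":
        return cls(seed=seed)

    @classmethod
    def degraded(cls, seed: int) -> "SynthesisParams":
        return cls(
            seed=seed,
            gain_jitter=0.2,
            offset_jitter=15.0,
            gradient_amplitude=0.3,
            noise_sigma=(3.0, 8.0),
            profile="degraded",
        )


def sample_shape(params: SynthesisParams, rng: np.random.Generator) -> np.ndarray:
    """One deformed template: smooth-mode jitter plus similarity jitter."""
    template = generate_template()
    modes = _deformation_modes(template)
    w = rng.normal(0.0, params.shape_jitter, size=len(params.shape_jitter))
    pts = template + np.einsum("m,mnd->nd", w, modes)
    s = 1.0 + rng.uniform(-params.scale_jitter, params.scale_jitter)
    th = rng.uniform(-params.rotation_jitter, params.rotation_jitter)
    t = rng.uniform(-params.translation_jitter, params.translation_jitter, size=2)
    c, d = s * np.cos(th), s * np.sin(th)
    center = np.array([_CX, _CY])
    return (pts - center) @ np.array([[c, d], [-d, c]]) + center + t


def render_ear_image(landmarks, params: SynthesisParams, rng=None,
                     scheme=None, atlas=None):
    """Render a grayscale ear image for a landmark set.

    Returns ``(image, landmarks)``; the ground-truth landmarks are returned
    unchanged.  With ``rng=None`` (or noise/illumination jitter zero) the
    rendering is deterministic in the landmarks.
    """
    from skimage.draw import polygon as draw_polygon

    scheme = scheme or scheme_mod.load_scheme()
    atlas = atlas or scheme_mod.load_atlas()
    lm = np.asarray(landmarks, dtype=float).reshape(-1, 2)
    h, w = params.image_size
    img = np.full((h, w), _BACKGROUND)

    outline_idx = list(range(36)) + list(scheme.earlobe_contour_indices)
    outer = lm[outline_idx]
    rr, cc = draw_polygon(outer[:, 1], outer[:, 0], shape=(h, w))
    img[rr, cc] = _SKIN

    for name, poly in build_region_polygons(lm, scheme, atlas).items():
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        img[rr, cc] = REGION_INTENSITY[name]

    img = _darken_ridges(img, lm)
    img = ndimage.gaussian_filter(img, params.blur_sigma)

    gain, offset = 1.0, 0.0
    plane = 1.0
    sigma = params.noise_sigma[0]
    if rng is not None:
        gain = 1.0 + rng.uniform(-params.gain_jitter, params.gain_jitter)
        offset = rng.uniform(-params.offset_jitter, params.offset_jitter)
        gx = rng.uniform(-params.gradient_amplitude, params.gradient_amplitude)
        gy = rng.uniform(-params.gradient_amplitude, params.gradient_amplitude)
        xs = (np.arange(w) / w - 0.5)[None, :]
        ys = (np.arange(h) / h - 0.5)[:, None]
        plane = 1.0 + gx * xs + gy * ys
        sigma = rng.uniform(*params.noise_sigma)
        img = img * gain * plane + offset + rng.normal(0.0, sigma, size=img.shape)
    return np.clip(img, 0, 255), lm


def _darken_ridges(img, lm):
    """Multiplicative darkening along the inner ridge polylines."""
    import shapely.geometry as sgeom
    from skimage.draw import polygon as draw_polygon

    out = img.copy()
    for idx, width, factor in (
        (range(36, 56), 2.5, 0.72),   # inner helix edge groove
        (range(56, 68), 2.5, 0.78),   # antihelix ridge shadow
    ):
        line = sgeom.LineString([tuple(p) for p in lm[list(idx)]])
        buf = line.buffer(width)
        coords = np.asarray(buf.exterior.coords)
        rr, cc = draw_polygon(coords[:, 1], coords[:, 0], shape=img.shape)
        out[rr, cc] *= factor
    return out


def ground_truth_box(landmarks) -> dict:
    """Boundary calibration (left/right/top/bottom pixel extremes)."""
    lm = np.asarray(landmarks, dtype=float).reshape(-1, 2)
    return {
        "left": float(lm[:, 0].min()),
        "right": float(lm[:, 0].max()),
        "top": float(lm[:, 1].min()),
        "bottom": float(lm[:, 1].max()),
    }


def generate_sample(params: SynthesisParams, rng: np.random.Generator):
    """One (image, landmarks, calibration-box) triple."""
    lm = sample_shape(params, rng)
    img, _ = render_ear_image(lm, params, rng=rng)
    return img, lm, ground_truth_box(lm)


def generate_dataset(n: int, params: SynthesisParams, out_dir=None, seed=None):
    """Generate *n* samples; optionally write PNG + PTS/JSON + calibration JSON.

    Returns ``(images, landmark_sets, boxes)``.  With ``out_dir`` given, the
    files ``ear_XXX.png / .pts / .json / _box.json`` are written and reruns
    with the same seed are byte-identical.
    """
    from earaam.io import write_landmarks

    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    images, lms, boxes = [], [], []
    for _ in range(n):
        img, lm, box = generate_sample(params, rng)
        images.append(img)
        lms.append(lm)
        boxes.append(box)
    if out_dir is not None:
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"n": n, "seed": seed, "profile": params.profile,
                "image_size": list(params.image_size)}
        (out / "dataset.json").write_text(json.dumps(meta, indent=2) + "\n")
        for i, (img, lm, box) in enumerate(zip(images, lms, boxes)):
            stem = f"ear_{i:03d}"
            Image.fromarray(np.round(img).astype(np.uint8)).save(out / f"{stem}.png")
            write_landmarks(lm, out / f"{stem}.pts", dialect="pts")
            write_landmarks(lm, out / f"{stem}.json", dialect="json")
            (out / f"{stem}_box.json").write_text(json.dumps(box, indent=2) + "\n")
    return images, lms, boxes
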