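"""Landmark and model file IO.

Landmark files come in two dialects: ibug-style PTS (written 1-based, read
1-based by default with a flag for 0-based files) and a JSON dialect with
explicit 0-based pixel coordinates.  Trained models are persisted in a
single NumPy container with a versioned JSON metadata header carrying the
hash of the landmark scheme they were trained under; loading verifies that
hash against the active scheme.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

CONTAINER_VERSION = 1


class LandmarkParseError(ValueError):
    """Malformed landmark file."""


class CompatibilityError(RuntimeError):
    """Model container version or scheme hash does not match."""


def scheme_hash(scheme) -> str:
    blob = json.dumps(scheme.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# -- landmarks ---------------------------------------------------------------

def write_landmarks(lm, path, dialect: str = "pts") -> None:
    """Write landmarks as PTS (1-based) or JSON (0-based)."""
    pts = np.asarray(lm, dtype=float).reshape(-1, 2)
    path = Path(path)
    if dialect == "pts":
        lines = ["version: 1", f"n_points: {len(pts)}", "{"]
        lines += [f"{x + 1:.6f} {y + 1:.6f}" for x, y in pts]
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "json":
        payload = {"coordinate_base": 0, "points": [[float(x), float(y)] for x, y in pts]}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown landmark dialect {dialect!r}")


def read_landmarks(path, n_points: int = 91, one_based=None) -> np.ndarray:
    """Read a PTS or JSON landmark file as (N, 2) 0-based pixel coordinates.

    For PTS, ``one_based=None`` follows the dialect default (1-based);
    pass False for files written with 0-based coordinates.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{") or path.suffix.lower() == ".json":
        try:
            payload = json.loads(text)
            pts = np.asarray(payload["points"], dtype=float)
            base = int(payload.get("coordinate_base", 0))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise LandmarkParseError(f"{path}: malformed JSON landmark file: {exc}") from exc
        pts = pts - base
    else:
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].lower().startswith("version"):
            raise LandmarkParseError(f"{path}: missing PTS version header")
        try:
            declared = int(lines[1].split(":")[1])
            body = lines[lines.index("{") + 1: lines.index("}")]
            pts = np.asarray([[float(v) for v in ln.split()] for ln in body])
        except (IndexError, ValueError) as exc:
            raise LandmarkParseError(f"{path}: malformed PTS file: {exc}") from exc
        if len(pts) != declared:
            raise LandmarkParseError(
                f"{path}: header declares {declared} points, file has {len(pts)}"
            )
        offset = 1.0 if (one_based is None or one_based) else 0.0
        pts = pts - offset
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise LandmarkParseError(f"{path}: expected (N, 2) coordinates")
    if n_points is not None and len(pts) != n_points:
        from earaam.shape import ShapeDimensionError

        raise ShapeDimensionError(
            f"{path}: expected {n_points} points, got {len(pts)}"
        )
    return pts


def read_calibration(path):
    """Boundary-calibration JSON {left, right, top, bottom} as a BoundingBox."""
    from earaam.detect import BoundingBox

    with open(path) as fh:
        d = json.load(fh)
    missing = {"left", "right", "top", "bottom"} - set(d)
    if missing:
        raise LandmarkParseError(f"{path}: calibration missing fields {sorted(missing)}")
    return BoundingBox.from_calibration(d)


def load_image(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path))


# -- model container ---------------------------------------------------------

def save_model(aam, path, scheme=None) -> None:
    """Persist a fitted :class:`~earaam.model.EarAAM` to a container file."""
    from earaam.scheme import load_scheme

    scheme = scheme or load_scheme()
    arrays = {}
    meta = {
        "container_version": CONTAINER_VERSION,
        "scheme_hash": scheme_hash(scheme),
        "params": aam.get_params(),
        "level_sigmas": list(aam.level_sigmas_),
        "n_levels_saved": len(aam.appearance_models_),
        "has_detector": aam.detector_ is not None,
    }
    sm = aam.shape_model_
    meta["shape_params"] = sm.get_params()
    for name in ("mean_shape_", "components_", "eigenvalues_", "all_eigenvalues_",
                 "weight_matrix_", "aligned_shapes_"):
        arrays[f"shape/{name}"] = getattr(sm, name)
    for i, app in enumerate(aam.appearance_models_):
        meta[f"appearance_params_{i}"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in app.get_params().items()
        }
        for name in ("reference_shape_", "mean_texture_", "components_",
                     "eigenvalues_", "all_eigenvalues_"):
            arrays[f"appearance{i}/{name}"] = getattr(app, name)
        arrays[f"appearance{i}/triangles"] = app.mesh_.triangles
    if aam.detector_ is not None:
        det = aam.detector_
        meta["detector_params"] = det.get_params()
        arrays["detector/coef"] = det.svm_.coef_
        arrays["detector/intercept"] = det.svm_.intercept_
        arrays["detector/classes"] = det.svm_.classes_
        arrays["detector/aspect"] = np.array([det.aspect_])
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_model(path, scheme=None):
    """Load a model container; verifies version and scheme hash."""
    from sklearn.svm import LinearSVC

    from earaam.appearance import EarAppearanceModel, PiecewiseAffineWarper, TriangleMesh
    from earaam.detect import EarDetector
    from earaam.fitter import AAMFitter
    from earaam.model import EarAAM
    from earaam.scheme import load_scheme
    from earaam.shape import EarShapeModel

    scheme = scheme or load_scheme()
    with np.load(path, allow_pickle=False) as data:
        if "__meta__" not in data:
            raise CompatibilityError(f"{path}: not an earaam model container")
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("container_version") != CONTAINER_VERSION:
            raise CompatibilityError(
                f"{path}: container version {meta.get('container_version')} "
                f"!= supported {CONTAINER_VERSION}"
            )
        if meta["scheme_hash"] != scheme_hash(scheme):
            raise CompatibilityError(
                f"{path}: model was trained under a different landmark scheme"
            )
        try:
            sm = EarShapeModel(**meta["shape_params"])
            for name in ("mean_shape_", "components_", "eigenvalues_",
                         "all_eigenvalues_", "weight_matrix_", "aligned_shapes_"):
                setattr(sm, name, data[f"shape/{name}"])
            sm.n_points_ = len(sm.mean_shape_) // 2
            sm.n_components_ = len(sm.components_)
            sm.training_poses_ = None

            aam = EarAAM(**meta["params"])
            aam.shape_model_ = sm
            aam.level_sigmas_ = list(meta["level_sigmas"])
            aam.appearance_models_ = []
            aam.fitters_ = []
            for i in range(meta["n_levels_saved"]):
                params = dict(meta[f"appearance_params_{i}"])
                params["exclusion_list"] = tuple(
                    tuple(t) for t in params.get("exclusion_list", [])
                )
                app = EarAppearanceModel(**params)
                for name in ("reference_shape_", "mean_texture_", "components_",
                             "eigenvalues_", "all_eigenvalues_"):
                    setattr(app, name, data[f"appearance{i}/{name}"])
                app.n_components_ = len(app.components_)
                app.mesh_ = TriangleMesh(data[f"appearance{i}/triangles"])
                app.warper_ = PiecewiseAffineWarper(app.reference_shape_, app.mesh_)
                aam.appearance_models_.append(app)
                aam.fitters_.append(AAMFitter(sm, app))
            aam.appearance_model_ = aam.appearance_models_[-1]

            aam.detector_ = None
            if meta["has_detector"]:
                det = EarDetector(**meta["detector_params"])
                svm = LinearSVC(C=det.C, random_state=det.random_state)
                svm.coef_ = data["detector/coef"]
                svm.intercept_ = data["detector/intercept"]
                svm.classes_ = data["detector/classes"]
                det.svm_ = svm
                det.aspect_ = float(data["detector/aspect"][0])
                det.descriptor_length_ = svm.coef_.shape[1]
                aam.detector_ = det
        except KeyError as exc:
            raise CompatibilityError(f"{path}: container missing array {exc}") from exc
    return aam
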