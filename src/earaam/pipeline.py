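"""End-to-end pipeline: detect -> initialize -> fit -> reconstruct earlobe ->
build regions -> segment, with a per-stage JSON report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from earaam import geometry
from earaam.fitter import FitConfig
from earaam.scheme import load_acupoints, load_atlas, load_scheme

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "scheme", "atlas", "acupoints", "model", "output_dir", "log_level", "fit",
}
_KNOWN_FIT_KEYS = {"max_iterations", "tol_shape", "tol_residual", "verbose"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (JSON file with CLI overrides)."""

    scheme: str = None
    atlas: str = None
    acupoints: str = None
    model: str = None
    output_dir: str = "."
    log_level: str = "INFO"
    fit: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        unknown_fit = set(raw.get("fit", {})) - _KNOWN_FIT_KEYS
        if unknown_fit:
            raise ValueError(f"{path}: unknown fit keys {sorted(unknown_fit)}")
        cfg = cls(**raw)
        for key in ("scheme", "atlas", "acupoints", "model"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{path}: {key} file {val!r} does not exist")
        return cfg

    def fit_config(self) -> FitConfig:
        return FitConfig(**self.fit)


def run_pipeline(image, aam, scheme=None, atlas=None, fit_config=None, box=None):
    """Run every stage on one image.

    Returns ``(report, artifacts)``: the report maps stage name to
    ``{status, seconds, ...}`` (later stages are skipped after a failure);
    artifacts hold the fit result, earlobe reconstruction, region polygons,
    label mask and overlay for the stages that ran.
    """
    scheme = scheme or load_scheme()
    atlas = atlas or load_atlas()
    report = {"stages": {}, "ok": False}
    artifacts = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        entry = {"status": "skipped"}
        report["stages"][name] = entry
        try:
            out = fn()
        except Exception as exc:  # report and halt the pipeline
            entry.update(status="failed", error=str(exc),
                         seconds=round(time.perf_counter() - t0, 4))
            raise
        entry.update(status="ok", seconds=round(time.perf_counter() - t0, 4))
        return out

    try:
        if box is None:
            det_box = stage("detect", lambda: aam.detector_.detect(image)
                            if aam.detector_ is not None else None)
            if det_box is None:
                report["stages"]["detect"].update(status="failed",
                                                  error="no ear detected")
                return report, artifacts
        else:
            det_box = box
            report["stages"]["detect"] = {"status": "ok", "seconds": 0.0,
                                          "note": "box supplied"}
        report["stages"]["detect"]["box"] = [det_box.x, det_box.y,
                                             det_box.w, det_box.h]

        init = stage("initialize", lambda: aam.initialize(image, box=det_box))
        result = stage("fit", lambda: aam.predict(image, init=init,
                                                  config=fit_config))
        artifacts["fit_result"] = result
        report["stages"]["fit"].update(
            converged=bool(result.converged), reason=result.reason,
            iterations=int(result.iterations),
            final_residual=float(result.final_residual),
        )

        def _reconstruct():
            contour = result.landmarks[list(scheme.earlobe_contour_indices)]
            return geometry.reconstruct_earlobe(geometry.densify_earlobe(contour))

        recon = stage("reconstruct_earlobe", _reconstruct)
        artifacts["earlobe"] = recon

        polys = stage("build_regions",
                      lambda: geometry.build_region_polygons(result.landmarks,
                                                             scheme, atlas))
        artifacts["regions"] = polys
        mask, overlay = stage("segment",
                              lambda: geometry.segment_regions(image, polys))
        artifacts["mask"], artifacts["overlay"] = mask, overlay
        report["ok"] = True
    except Exception:
        logger.exception("pipeline stage failed")
    return report, artifacts


def write_artifacts(report, artifacts, out_dir, stem="result"):
    """Write the report, landmarks, mask and overlay under *out_dir*."""
    from PIL import Image

    from earaam.io import write_landmarks

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{stem}_report.json").write_text(json.dumps(report, indent=2) + "\n")
    if "fit_result" in artifacts:
        write_landmarks(artifacts["fit_result"].landmarks, out / f"{stem}.pts")
        write_landmarks(artifacts["fit_result"].landmarks,
                        out / f"{stem}.json", dialect="json")
    if "mask" in artifacts:
        Image.fromarray(artifacts["mask"], mode="P").save(out / f"{stem}_mask.png")
    if "overlay" in artifacts:
        Image.fromarray(artifacts["overlay"]).save(out / f"{stem}_overlay.png")
    if "regions" in artifacts:
        geo = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {"region": name},
                 "geometry": {"type": "Polygon",
                              "coordinates": [[[float(x), float(y)]
                                               for x, y in poly] +
                                              [[float(poly[0][0]),
                                                float(poly[0][1])]]]}}
                for name, poly in artifacts["regions"].items()
            ],
        }
        (out / f"{stem}_regions.json").write_text(json.dumps(geo) + "\n")
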