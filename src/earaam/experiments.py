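"""Benchmark experiments on synthetic data.

These drive the package's reproducibility checks: a landmark-accuracy
benchmark (train on standard-profile synthetic images, fit held-out standard
and degraded images end-to-end from detected boxes), a parameter-recovery
experiment on model-generated images, and the earlobe nine-area division on
an analytic semicircular lobe contour.
"""

from __future__ import annotations

import numpy as np

from earaam.fitter import FitConfig
from earaam.geometry import (densify_earlobe, divide_earlobe_nine,
                             reconstruct_earlobe, _polygon_area)
from earaam.model import EarAAM
from earaam.synthetic import SynthesisParams, generate_dataset

ACCEPT_PX = 6.0  # expert-acceptability threshold on mean landmark error


def run_landmark_benchmark(seed: int, n_train: int = 40, n_standard: int = 10,
                           n_degraded: int = 20, fit_config: FitConfig = None):
    """Train an AAM on standard synthetic images and fit held-out images.

    Every held-out image runs the full pipeline: HOG+SVM detection,
    mean-shape initialization from the detected box, coarse-to-fine
    inverse-compositional fitting.  Returns a dict with the trained model and
    per-image mean landmark errors and convergence flags for both the
    standard and the degraded profile.
    """
    train_imgs, train_lms, train_boxes = generate_dataset(
        n_train, SynthesisParams.standard(seed))
    aam = EarAAM(n_levels=2).fit(train_imgs, train_lms, boxes=train_boxes)

    out = {"aam": aam, "seed": seed, "n_train": n_train}
    for profile, n, params_fn in (
        ("standard", n_standard, SynthesisParams.standard),
        ("degraded", n_degraded, SynthesisParams.degraded),
    ):
        if n == 0:
            continue
        offset = 1000 if profile == "standard" else 2000
        imgs, lms, _ = generate_dataset(n, params_fn(seed + offset))
        errors, converged, detected = [], [], []
        for img, lm in zip(imgs, lms):
            box = aam.detector_.detect(img)
            detected.append(box is not None)
            if box is None:
                errors.append(np.inf)
                converged.append(False)
                continue
            res = aam.predict(img, box=box, config=fit_config)
            errors.append(float(np.linalg.norm(res.landmarks - lm, axis=1).mean()))
            converged.append(bool(res.converged))
        out[profile] = {
            "errors": np.asarray(errors),
            "converged": np.asarray(converged),
            "detected": np.asarray(detected),
            "n": n,
        }
    return out


def accuracy_summary(result: dict, profile: str) -> dict:
    """Acceptance-style summary: mean error, success and convergence rates."""
    r = result[profile]
    ok = r["errors"] <= ACCEPT_PX
    return {
        "mean_error_px": float(np.mean(r["errors"][np.isfinite(r["errors"])]))
        if np.any(np.isfinite(r["errors"])) else float("inf"),
        "success_rate_pct": 100.0 * float(np.mean(ok)),
        "converged_ok_pct": 100.0 * float(np.mean(ok & r["converged"])),
        "n": int(r["n"]),
    }


def parameter_recovery_experiment(aam: EarAAM):
    """Fit a model-generated image from a similarity-jittered initialization.

    The ground-truth shape weights are set deterministically to +-2 standard
    deviations of each retained mode; the initialization is the truth scaled
    by 1.05 and shifted by (5, -4) px.  Returns (relative weight error,
    mean landmark error in px).
    """
    from earaam.appearance import PiecewiseAffineWarper

    fitter = aam.fitters_[-1]
    app = fitter.appearance_model
    p_true = np.zeros(fitter.Q.shape[1])
    p_true[2], p_true[3] = 250.0, 250.0
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(p_true) - 4)])
    p_true[4:] = 2.0 * signs * np.sqrt(aam.shape_model_.eigenvalues_) * fitter.param_scale

    target = fitter.landmarks_from_params(p_true)
    tex = app.mean_texture_
    tex_img = app.warper_.to_image(tex, fill=tex.mean())
    render = PiecewiseAffineWarper(target, app.mesh_, frame_shape=(500, 500))
    img = np.full((500, 500), float(tex.mean()))
    img[render.mask] = render.sample(tex_img, app.reference_shape_)
    img = 40.0 * img + 128.0

    center = target.mean(axis=0)
    init = (target - center) * 1.05 + center + np.array([5.0, -4.0])
    res = fitter.fit(img, init, FitConfig(max_iterations=100))
    rel = float(np.linalg.norm(res.params[4:] - p_true[4:])
                / np.linalg.norm(p_true[4:]))
    err = float(np.linalg.norm(res.landmarks - target, axis=1).mean())
    return rel, err


def earlobe_division_experiment(r: float = 60.0, k_n: int = 20):
    """Nine-area division of an analytic semicircular lobe contour.

    Returns (number of sub-areas, relative area-conservation error).
    """
    ang = np.linspace(np.pi, 2 * np.pi, 9)
    contour = np.column_stack([100.0 + r * np.cos(ang), 50.0 + r * np.sin(-ang)])
    recon = reconstruct_earlobe(densify_earlobe(contour, k_n=k_n))
    cells = divide_earlobe_nine(recon)
    total = sum(abs(_polygon_area(c)) for c in cells)
    whole = abs(_polygon_area(recon.dense_contour))
    return len(cells), abs(total - whole) / whole
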