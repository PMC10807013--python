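"""EarAAM: the trained ear model (shape + appearance + detector) as one
estimator.

``fit`` consumes training images with 91-point annotations (and optional
calibration boxes for the detector); ``predict`` runs detection, mean-shape
initialization and the coarse-to-fine inverse-compositional search on a new
image, returning a :class:`~earaam.fitter.FitResult`.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from earaam.appearance import EarAppearanceModel, to_grayscale
from earaam.detect import BoundingBox, EarDetector, initialize_shape
from earaam.fitter import AAMFitter, FitConfig, FitResult
from earaam.shape import EarShapeModel


class EarAAM(BaseEstimator):
    """Complete active-appearance ear model.

    Parameters
    ----------
    variance_retained_shape, variance_retained_texture : float
        PCA variance retained by the shape / texture models.
    reference_extent : float
        Longest bounding-box side of the appearance reference frame (px).
    n_levels : int
        Fitting levels; with 2 levels the first pass runs on a Gaussian-
        smoothed image against an appearance model trained on equally
        smoothed images (widens the convergence basin), the last level on the
        raw image.
    coarse_sigma : float
        Smoothing of the coarse level (px).
    train_detector : bool
        Train the HOG+SVM detector from the calibration boxes passed to fit.
    """

    def __init__(self, variance_retained_shape=0.98, variance_retained_texture=0.98,
                 reference_extent=150.0, weight_mode="all_pairs", n_levels=2,
                 coarse_sigma=4.0, exclusion_list=(), train_detector=True,
                 negatives_per_image=4, random_state=0):
        self.variance_retained_shape = variance_retained_shape
        self.variance_retained_texture = variance_retained_texture
        self.reference_extent = reference_extent
        self.weight_mode = weight_mode
        self.n_levels = n_levels
        self.coarse_sigma = coarse_sigma
        self.exclusion_list = exclusion_list
        self.train_detector = train_detector
        self.negatives_per_image = negatives_per_image
        self.random_state = random_state

    def _level_sigmas(self):
        if self.n_levels <= 1:
            return [0.0]
        step = self.coarse_sigma / (self.n_levels - 1)
        return [self.coarse_sigma - i * step for i in range(self.n_levels)]

    def fit(self, images, landmark_sets, boxes=None, y=None):
        """Train shape, appearance levels and (optionally) the detector."""
        images = [to_grayscale(im) for im in images]
        lms = [np.asarray(l, dtype=float).reshape(-1, 2) for l in landmark_sets]
        self.shape_model_ = EarShapeModel(
            variance_retained=self.variance_retained_shape, weight_mode=self.weight_mode
        ).fit(lms)
        self.level_sigmas_ = self._level_sigmas()
        self.appearance_models_ = []
        self.fitters_ = []
        for sigma in self.level_sigmas_:
            level_imgs = (
                [ndimage.gaussian_filter(im, sigma) for im in images] if sigma else images
            )
            app = EarAppearanceModel(
                variance_retained=self.variance_retained_texture,
                reference_extent=self.reference_extent,
                exclusion_list=self.exclusion_list,
            ).fit(level_imgs, lms, shape_model=self.shape_model_)
            self.appearance_models_.append(app)
            self.fitters_.append(AAMFitter(self.shape_model_, app))
        self.appearance_model_ = self.appearance_models_[-1]

        self.detector_ = None
        if self.train_detector and boxes is not None:
            self.detector_ = self._fit_detector(images, boxes)
        return self

    def _fit_detector(self, images, boxes) -> EarDetector:
        rng = np.random.default_rng(self.random_state)
        positives, negatives = [], []
        for img, box in zip(images, boxes):
            bb = box if isinstance(box, BoundingBox) else BoundingBox.from_calibration(box)
            positives.append((img, bb))
            h, w = img.shape
            tries = 0
            added = 0
            while added < self.negatives_per_image and tries < 50:
                tries += 1
                side = int(rng.uniform(0.3, 0.9) * min(h, w))
                x = int(rng.uniform(0, w - side))
                y0 = int(rng.uniform(0, h - side))
                cand = BoundingBox(x, y0, side, side)
                if cand.iou(bb) < 0.2:
                    negatives.append(img[y0: y0 + side, x: x + side])
                    added += 1
        det = EarDetector(random_state=self.random_state)
        return det.fit(positives, negatives)

    # -- inference -----------------------------------------------------------

    def initialize(self, image, box=None):
        """Initial landmarks: mean shape placed in a detected (or given) box."""
        if box is None:
            if self.detector_ is None:
                raise ValueError("no detector trained and no box given")
            box = self.detector_.detect(image)
            if box is None:
                return None
        if not isinstance(box, BoundingBox):
            box = BoundingBox.from_calibration(box) if isinstance(box, dict) else BoundingBox(*box)
        return initialize_shape(box, self.shape_model_)

    def predict(self, image, box=None, init=None, config: FitConfig = None) -> FitResult:
        """Detect (unless a box/init is given) and fit; coarse-to-fine."""
        img = to_grayscale(image)
        if init is None:
            init = self.initialize(img, box=box)
            if init is None:
                raise RuntimeError("ear detection returned no box")
        current = np.asarray(init, dtype=float).reshape(-1, 2)
        result = None
        for sigma, fitter in zip(self.level_sigmas_, self.fitters_):
            level = ndimage.gaussian_filter(img, sigma) if sigma else img
            result = fitter.fit(level, current, config)
            current = result.landmarks
        return result
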