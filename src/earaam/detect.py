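"""Coarse ear localization: HOG descriptors + linear SVM over sliding windows.

The detector is trained from boundary-calibrated positive boxes (resized to a
fixed window) and negative patches cut from the same images; at test time a
sliding window is scored over an image pyramid, candidate boxes above the
decision threshold are merged by non-maximum suppression, and the top box
seeds the fit by similarity-placing the mean shape inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import hog as skimage_hog
from skimage.transform import resize
from sklearn.base import BaseEstimator
from sklearn.svm import LinearSVC

from earaam.appearance import to_grayscale


@dataclass
class BoundingBox:
    """Axis-aligned detection box, 0-based pixels, top-left anchored."""

    x: float
    y: float
    w: float
    h: float
    score: float = 0.0

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("bounding box must have positive width and height")

    def clip(self, image_shape) -> "BoundingBox":
        ih, iw = image_shape[:2]
        x0, y0 = max(self.x, 0.0), max(self.y, 0.0)
        x1, y1 = min(self.x + self.w, iw), min(self.y + self.h, ih)
        return BoundingBox(x0, y0, max(x1 - x0, 1e-6), max(y1 - y0, 1e-6), self.score)

    def iou(self, other: "BoundingBox") -> float:
        x0 = max(self.x, other.x)
        y0 = max(self.y, other.y)
        x1 = min(self.x + self.w, other.x + other.w)
        y1 = min(self.y + self.h, other.y + other.h)
        inter = max(x1 - x0, 0.0) * max(y1 - y0, 0.0)
        union = self.w * self.h + other.w * other.h - inter
        return inter / union if union > 0 else 0.0

    @classmethod
    def from_calibration(cls, calib: dict) -> "BoundingBox":
        """Box from {left, right, top, bottom} pixel-extreme calibration."""
        return cls(
            x=float(calib["left"]),
            y=float(calib["top"]),
            w=float(calib["right"]) - float(calib["left"]),
            h=float(calib["bottom"]) - float(calib["top"]),
        )


@dataclass
class HogParams:
    cell_size: int = 8
    block_size: int = 2
    orientations: int = 9


def compute_hog(window, params: HogParams = None) -> np.ndarray:
    """Block-normalized (L2-hys) orientation-histogram descriptor of a patch."""
    params = params or HogParams()
    win = to_grayscale(window)
    return skimage_hog(
        win,
        orientations=params.orientations,
        pixels_per_cell=(params.cell_size, params.cell_size),
        cells_per_block=(params.block_size, params.block_size),
        block_norm="L2-Hys",
        feature_vector=True,
    )


class EarDetector(BaseEstimator):
    """Sliding-window HOG + linear SVM ear detector.

    Parameters follow common pedestrian-detector defaults: 96 x 96 window,
    8 x 8 cells, 2 x 2 blocks, 9 unsigned orientation bins, pyramid scale
    factor 1.25, stride 16, NMS IoU 0.3.
    """

    def __init__(self, window_size=96, cell_size=8, block_size=2, orientations=9,
                 scale_factor=1.25, stride=16, nms_iou=0.3, threshold=0.0,
                 C=1.0, random_state=0):
        self.window_size = window_size
        self.cell_size = cell_size
        self.block_size = block_size
        self.orientations = orientations
        self.scale_factor = scale_factor
        self.stride = stride
        self.nms_iou = nms_iou
        self.threshold = threshold
        self.C = C
        self.random_state = random_state

    @property
    def hog_params(self) -> HogParams:
        return HogParams(self.cell_size, self.block_size, self.orientations)

    def _window_descriptor(self, patch) -> np.ndarray:
        win = np.asarray(to_grayscale(patch), dtype=float)
        if win.shape != (self.window_size, self.window_size):
            win = resize(win, (self.window_size, self.window_size),
                         anti_aliasing=True, preserve_range=True)
        return compute_hog(win, self.hog_params)

    def fit(self, positives, negatives, y=None):
        """Train from positive (image, BoundingBox) pairs and negative patches.

        ``positives``: sequence of ``(image, BoundingBox)``; the box content
        is resized to the training window.  ``negatives``: image patches.
        """
        if len(positives) == 0 or len(negatives) == 0:
            raise ValueError("need both positive and negative examples")
        X, y_lab = [], []
        for img, box in positives:
            gray = to_grayscale(img)
            # square crop around the calibration box so it matches the
            # square sliding window's geometry (no anisotropic squeeze)
            side = 1.05 * max(box.w, box.h)
            cx, cy = box.x + box.w / 2.0, box.y + box.h / 2.0
            sq = BoundingBox(cx - side / 2.0, cy - side / 2.0, side, side).clip(gray.shape)
            patch = gray[int(sq.y): int(sq.y + sq.h), int(sq.x): int(sq.x + sq.w)]
            X.append(self._window_descriptor(patch))
            y_lab.append(1)
        for patch in negatives:
            X.append(self._window_descriptor(patch))
            y_lab.append(0)
        X = np.asarray(X)
        y_lab = np.asarray(y_lab)
        if len(np.unique(y_lab)) < 2:
            raise ValueError("training needs both classes")
        self.aspect_ = float(np.mean([box.w / box.h for _, box in positives]))
        self.svm_ = LinearSVC(C=self.C, random_state=self.random_state)
        self.svm_.fit(X, y_lab)
        self.training_accuracy_ = float(self.svm_.score(X, y_lab))
        self.descriptor_length_ = X.shape[1]
        return self

    def decision_value(self, patch) -> float:
        return float(self.svm_.decision_function([self._window_descriptor(patch)])[0])

    def detect_all(self, image):
        """All NMS-surviving boxes above threshold, best first."""
        gray = to_grayscale(image)
        win = self.window_size
        if min(gray.shape) < win:
            raise ValueError("image smaller than the detection window")
        candidates = []
        scale = 1.0
        level = gray
        while min(level.shape) >= win:
            descs, boxes = [], []
            for yy in range(0, level.shape[0] - win + 1, self.stride):
                for xx in range(0, level.shape[1] - win + 1, self.stride):
                    descs.append(compute_hog(level[yy: yy + win, xx: xx + win],
                                             self.hog_params))
                    boxes.append((xx, yy))
            if descs:
                scores = self.svm_.decision_function(np.asarray(descs))
                for (xx, yy), sc in zip(boxes, scores):
                    if sc > self.threshold:
                        candidates.append(
                            BoundingBox(xx * scale, yy * scale, win * scale,
                                        win * scale, float(sc))
                        )
            scale *= self.scale_factor
            new_shape = (max(int(round(gray.shape[0] / scale)), 1),
                         max(int(round(gray.shape[1] / scale)), 1))
            if min(new_shape) < win:
                break
            level = resize(gray, new_shape, anti_aliasing=True, preserve_range=True)
        return [self._unsquare(b) for b in _nms(candidates, self.nms_iou)]

    def _unsquare(self, box: BoundingBox) -> BoundingBox:
        """Undo the square training crop: restore the mean calibration aspect."""
        aspect = getattr(self, "aspect_", 1.0)
        side = box.w / 1.05
        if aspect <= 1.0:
            h, w = side, side * aspect
        else:
            w, h = side, side / aspect
        cx, cy = box.x + box.w / 2.0, box.y + box.h / 2.0
        return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h, box.score)

    def detect(self, image):
        """Top-scoring box, or None if nothing passes the threshold."""
        boxes = self.detect_all(image)
        return boxes[0] if boxes else None

    def predict(self, images):
        return [self.detect(img) for img in images]


def _nms(boxes, iou_threshold):
    boxes = sorted(boxes, key=lambda b: b.score, reverse=True)
    kept = []
    for b in boxes:
        if all(b.iou(k) <= iou_threshold for k in kept):
            kept.append(b)
    return kept


def detect_ear(image, detector: EarDetector):
    """Functional wrapper: top detection box or None."""
    return detector.detect(image)


def initialize_shape(box: BoundingBox, shape_model) -> np.ndarray:
    """Mean shape similarity-placed inside a detection box.

    The mean shape is scaled (isotropically, by the larger-fit rule so it is
    fully contained) and centered on the box center.
    """
    mean_pts = shape_model.mean_shape_.reshape(-1, 2)
    lo, hi = mean_pts.min(axis=0), mean_pts.max(axis=0)
    extent = hi - lo
    scale = min(box.w / extent[0], box.h / extent[1])
    center = np.array([box.x + box.w / 2.0, box.y + box.h / 2.0])
    mean_center = (lo + hi) / 2.0
    return (mean_pts - mean_center) * scale + center


def train_detector(positive_boxes, negative_patches, **kwargs) -> EarDetector:
    """Functional wrapper over :class:`EarDetector.fit`."""
    det = EarDetector(**kwargs)
    return det.fit(positive_boxes, negative_patches)
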