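"""Fiber / non-fiber pixel classification of SEM micrographs.

Two routes are provided:

* a trainable per-pixel classifier (multiscale intensity / gradient /
  Hessian features feeding a seeded random forest), mirroring the
  interactive machine-learning segmentation used on cryo-SEM images of
  decellularized tumor matrix, and
* a deterministic thresholding fallback (Otsu or fixed cut) for pipelines
  without training annotations.

Conventions: images are 2-D float rasters in [0, 1]; masks are boolean
with ``True`` = fiber.  Fibers are assumed bright on a dark background
(secondary-electron contrast); pass ``fibers_bright=False`` to invert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "GrayscaleImage",
    "BinaryMask",
    "PixelClassifier",
    "adjust_contrast",
    "compute_feature_stack",
    "train_pixel_classifier",
    "classify_pixels",
    "threshold_segment",
    "DEFAULT_SCALES",
    "DEFAULT_CONTRAST_PERCENTILES",
]

#: Default smoothing scales (px) for the per-pixel feature stack.
DEFAULT_SCALES = (1.0, 2.0, 4.0)

#: Default percentile pair for contrast stretching; robust to a few
#: saturated pixels.
DEFAULT_CONTRAST_PERCENTILES = (1.0, 99.0)


@dataclass
class GrayscaleImage:
    """A calibrated 2-D intensity raster.

    Parameters
    ----------
    pixels
        2-D float array with values in [0, 1].
    pixel_size
        Physical size of one pixel in nm, if known.
    magnification
        Optional instrument magnification, metadata only.
    """

    pixels: np.ndarray
    pixel_size: float | None = None
    magnification: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("image must be 2-D and at least 2x2")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("image values must lie in [0, 1]; rescale on load")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Fiber / non-fiber classification of an image (``True`` = fiber)."""

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def fiber_fraction(self) -> float:
        return float(self.pixels.mean())


def adjust_contrast(
    image: GrayscaleImage,
    low_pct: float = DEFAULT_CONTRAST_PERCENTILES[0],
    high_pct: float = DEFAULT_CONTRAST_PERCENTILES[1],
) -> GrayscaleImage:
    """Linearly stretch contrast so the given percentiles map to 0 and 1.

    Values outside the percentile window are clipped.  A constant image
    has no contrast to stretch and is returned unchanged with a warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(image.pixels, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("image has no contrast to stretch; returned unchanged")
        return GrayscaleImage(image.pixels.copy(), image.pixel_size, image.magnification)
    stretched = np.clip((image.pixels - lo) / (hi - lo), 0.0, 1.0)
    return GrayscaleImage(stretched, image.pixel_size, image.magnification)


def compute_feature_stack(
    image: GrayscaleImage, scales: tuple[float, ...] = DEFAULT_SCALES
) -> np.ndarray:
    """Per-pixel feature vectors for trainable segmentation.

    For each scale ``s`` the stack holds the Gaussian-smoothed intensity,
    the Gaussian gradient magnitude and the largest Hessian eigenvalue at
    that scale, plus the raw intensity, giving ``1 + 3 * len(scales)``
    features per pixel.

    Returns
    -------
    ndarray of shape ``(rows, cols, n_features)``.
    """
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    img = image.pixels
    feats = [img]
    for s in scales:
        feats.append(ndi.gaussian_filter(img, s))
        feats.append(ndi.gaussian_gradient_magnitude(img, s))
        hrr = ndi.gaussian_filter(img, s, order=(2, 0))
        hrc = ndi.gaussian_filter(img, s, order=(1, 1))
        hcc = ndi.gaussian_filter(img, s, order=(0, 2))
        # largest Hessian eigenvalue in closed form (ridge response)
        feats.append(0.5 * (hrr + hcc + np.sqrt((hrr - hcc) ** 2 + 4 * hrc**2)))
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """A trained fiber/non-fiber pixel classifier.

    Bundles the fitted decision model with the feature configuration it
    was trained on, so prediction recomputes the identical feature stack.
    """

    model: RandomForestClassifier
    scales: tuple[float, ...]
    seed: int
    training_accuracy: float = field(default=float("nan"))


def train_pixel_classifier(
    image: GrayscaleImage,
    labels: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
    n_estimators: int = 100,
) -> PixelClassifier:
    """Train a random forest on sparsely annotated pixels.

    Parameters
    ----------
    labels
        Integer array of the image shape: 1 = fiber, 0 = non-fiber,
        -1 = unlabeled.  Both classes must be present.
    """
    labels = np.asarray(labels)
    if labels.shape != image.shape:
        raise ValueError("labels must have the image shape")
    annotated = labels >= 0
    present = set(np.unique(labels[annotated]).tolist())
    for cls, name in ((1, "fiber"), (0, "non-fiber")):
        if cls not in present:
            raise ValueError(f"training labels contain no {name!r} pixels")
    feats = compute_feature_stack(image, scales)
    x = feats[annotated]
    y = labels[annotated]
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(x, y)
    acc = float(model.score(x, y))
    return PixelClassifier(model=model, scales=tuple(scales), seed=seed, training_accuracy=acc)


def classify_pixels(image: GrayscaleImage, classifier: PixelClassifier) -> BinaryMask:
    """Label every pixel of ``image`` with the trained classifier."""
    feats = compute_feature_stack(image, classifier.scales)
    flat = feats.reshape(-1, feats.shape[-1])
    pred = classifier.model.predict(flat).reshape(image.shape)
    return BinaryMask(pred == 1, pixel_size=image.pixel_size)


def threshold_segment(
    image: GrayscaleImage,
    method: str = "otsu",
    fixed_value: float | None = None,
    fibers_bright: bool = True,
) -> BinaryMask:
    """Deterministic threshold segmentation (Otsu or a fixed cut).

    Fiber pixels are those above the threshold when ``fibers_bright``
    (the default polarity), below it otherwise.
    """
    if method == "otsu":
        if np.ptp(image.pixels) == 0:
            raise ValueError(
                "constant image: Otsu threshold undefined, use method='fixed'"
            )
        thr = float(threshold_otsu(image.pixels))
    elif method == "fixed":
        if fixed_value is None or not (0 < fixed_value < 1):
            raise ValueError("method 'fixed' requires fixed_value in (0, 1)")
        thr = float(fixed_value)
    else:
        raise ValueError(f"unknown method {method!r}")
    fiber = image.pixels > thr
    if not fibers_bright:
        fiber = ~fiber
    return BinaryMask(fiber, pixel_size=image.pixel_size)
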