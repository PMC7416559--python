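"""Structure-tensor orientation analysis of fibrous images.

Per-pixel orientation is obtained from the eigen-structure of the
Gaussian-smoothed structure tensor (the smoothed outer product of the
intensity gradient).  The dominant eigenvector of that tensor points
across a fiber (maximal intensity variation); the fiber axis reported
here is the perpendicular, minimal-variation direction.  Coherence
``(l1 - l2) / (l1 + l2)`` measures how anisotropic the local texture is
(1 for a perfect grating, 0 for isotropic texture), and energy
``l1 + l2`` separates structured pixels from flat background.

Angles are degrees in [-90, 90) with 0 deg along the +x (column) axis and
counter-clockwise positive in conventional math coordinates (y up), so a
horizontal fiber reads 0 deg and a vertical one folds to -90 deg.

Alignment of an angle sample is summarized by the nematic order
parameter: the magnitude of the mean doubled-angle unit vector, which is
1 for perfectly parallel fibers and 0 for an isotropic network,
respecting the 180-degree ambiguity of undirected fibers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk

from .segmentation import GrayscaleImage
from .fiber_architecture import Skeleton

__all__ = [
    "OrientationField",
    "OrientationDistribution",
    "AlignmentScore",
    "structure_tensor_field",
    "centerline_orientations",
    "orientation_distribution",
    "alignment_score",
    "DEFAULT_WINDOW_SIGMA",
    "DEFAULT_DILATION_PX",
]

#: Gaussian window (sigma, px) for structure-tensor smoothing.
DEFAULT_WINDOW_SIGMA = 7.0

#: Centerline dilation radius (px) before sampling orientations.
DEFAULT_DILATION_PX = 2


@dataclass
class OrientationField:
    """Per-pixel fiber angle (deg, NaN where undefined), coherence in
    [0, 1] and tensor energy."""

    angle: np.ndarray
    coherence: np.ndarray
    energy: np.ndarray


@dataclass
class OrientationDistribution:
    """Normalized angular histogram over [-90, 90) with its local peaks."""

    bin_edges: np.ndarray
    weights: np.ndarray
    peak_angles: list[float]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class AlignmentScore:
    """Nematic order parameter S in [0, 1] over n sampled orientations."""

    S: float
    n_samples: int


def structure_tensor_field(
    image: GrayscaleImage,
    window_sigma: float = DEFAULT_WINDOW_SIGMA,
    gradient_sigma: float = 1.0,
) -> OrientationField:
    """Per-pixel orientation, coherence and energy from the structure tensor.

    Gradients are centered differences after a small Gaussian pre-smooth;
    the gradient outer products are then smoothed with a Gaussian window
    of the given sigma and eigen-decomposed in closed form.
    """
    if window_sigma <= 0:
        raise ValueError("window_sigma must be positive")
    img = ndi.gaussian_filter(image.pixels, gradient_sigma)
    # row gradient points down the image; negate for math-convention y (up)
    grow, gcol = np.gradient(img)
    gx, gy = gcol, -grow
    jxx = ndi.gaussian_filter(gx * gx, window_sigma)
    jxy = ndi.gaussian_filter(gx * gy, window_sigma)
    jyy = ndi.gaussian_filter(gy * gy, window_sigma)
    energy = jxx + jyy
    disc = np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(energy > 0, disc / energy, 0.0)
    # gradient (max-variation) direction is 0.5*atan2(2Jxy, Jxx-Jyy);
    # the fiber axis is perpendicular, i.e. 0.5*atan2(-2Jxy, Jyy-Jxx)
    angle = np.degrees(0.5 * np.arctan2(-2 * jxy, jyy - jxx))
    angle = ((angle + 90) % 180) - 90
    angle = np.where(energy > 0, angle, np.nan)
    return OrientationField(angle=angle, coherence=np.clip(coherence, 0, 1), energy=energy)


def centerline_orientations(
    field: OrientationField,
    skeleton: Skeleton,
    dilation_px: int = DEFAULT_DILATION_PX,
    energy_floor: float | None = None,
) -> np.ndarray:
    """Sample field angles on the (dilated) fiber centerlines.

    The skeleton is enlarged by ``dilation_px`` to reduce single-pixel
    sampling error; pixels whose tensor energy falls below the floor
    (default: the median energy of the whole field) are excluded so that
    background swept in by the dilation does not dilute the sample.
    """
    if dilation_px < 0:
        raise ValueError("dilation_px must be non-negative")
    if not skeleton.pixels.any():
        warnings.warn("empty skeleton: no orientations sampled")
        return np.empty(0)
    support = skeleton.pixels
    if dilation_px > 0:
        support = dilation(support, disk(dilation_px))
    if energy_floor is None:
        energy_floor = float(np.median(field.energy))
    sel = support & (field.energy > energy_floor) & ~np.isnan(field.angle)
    return field.angle[sel]


def orientation_distribution(angles, n_bins: int = 36) -> OrientationDistribution:
    """Normalized angular histogram with circular peak detection.

    Peaks are bins strictly exceeding both neighbors under circular
    adjacency (the -90/+90 wrap is the same fiber direction).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    folded = ((angles + 90) % 180) - 90
    counts, edges = np.histogram(folded, bins=n_bins, range=(-90.0, 90.0))
    weights = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = [
        float(centers[i])
        for i in range(n_bins)
        if weights[i] > 0
        and weights[i] > weights[(i - 1) % n_bins]
        and weights[i] > weights[(i + 1) % n_bins]
    ]
    return OrientationDistribution(bin_edges=edges, weights=weights, peak_angles=peaks)


def alignment_score(angles) -> AlignmentScore:
    """Nematic order parameter of an angle sample (degrees)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    doubled = np.radians(2.0 * angles)
    s = float(np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean()))
    return AlignmentScore(S=s, n_samples=int(angles.size))


def mean_orientation(angles) -> float:
    """Circular mean of undirected angles (degrees in [-90, 90))."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    doubled = np.radians(2.0 * angles)
    mu = 0.5 * np.degrees(np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean()))
    return float(((mu + 90) % 180) - 90)
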