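"""Synthetic inputs with exact ground truth for every pipeline stage.

Real decellularized-tumor SEM images, rheometer sweeps and sequencing
tables are not redistributable, so each downstream stage is validated on
generated data whose ground truth is known by construction:

* SEM-like fibrous images: straight constant-width bars with angles
  drawn from a von Mises law on doubled angles (respecting the
  180-degree ambiguity of undirected fibers), rendered as bright fibers
  on a dark background, then Gaussian-blurred and corrupted with
  additive Gaussian noise.  The binary ground-truth mask and the exact
  pixel porosity are recorded before blur and noise.
* Cell outlines: discretized ellipses of controllable elongation with
  analytic area/perimeter/axes.
* Rheology sweeps: single-mode Maxwell element
  ``G'(w) = G w^2 t^2 / (1 + w^2 t^2)``,
  ``G''(w) = G w t / (1 + w^2 t^2)``, whose moduli cross at
  ``w = 1/t``; optional multiplicative log-normal noise keeps moduli
  positive.
* Two-condition expression tables with planted up/down protein-coding
  genes across a realistic biotype mix.
* Duplicate-spot cytokine arrays with background and reference spots.

All generators are pure functions of their spec (including its seed):
the same spec yields bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import ellipe

from .morphometry import CellOutline
from .rheology import RheologySweep
from .segmentation import BinaryMask, GrayscaleImage

__all__ = [
    "FiberImageSpec",
    "FiberRecord",
    "FiberGroundTruth",
    "MaxwellSpec",
    "ExpressionSimSpec",
    "CellOutlineTruth",
    "generate_fiber_image",
    "generate_cell_outlines",
    "generate_rheology_sweep",
    "generate_expression_table",
    "generate_cytokine_array",
    "render_fiber_mask",
    "DEFAULT_BIOTYPE_PROPORTIONS",
]

#: Angular-frequency grid of the emulated instrument sweep (rad/s).
DEFAULT_FREQUENCY_GRID = tuple(np.geomspace(0.628, 62.8, 21))

#: Biotype mix of the simulated gene tables.  Protein-coding transcripts
#: dominate gene-level tables; the five non-coding classes are the ones a
#: coding-only screen removes.
DEFAULT_BIOTYPE_PROPORTIONS = {
    "protein_coding": 0.70,
    "lincRNA": 0.10,
    "miRNA": 0.05,
    "3prime_overlapping_ncRNA": 0.02,
    "processed_pseudogene": 0.08,
    "antisense": 0.05,
}


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


# --------------------------------------------------------------------------
# fibrous SEM-like images
# --------------------------------------------------------------------------

@dataclass
class FiberImageSpec:
    """Parameters of one synthetic fibrous image.

    ``orientation_kappa`` is the von Mises concentration on the
    doubled-angle circle: 0 gives an isotropic network, large values a
    tightly aligned one (>= 1e6 is treated as exactly aligned at
    ``orientation_mu``).  Intensities are on [0, 1]; ``noise_sd`` is the
    standard deviation of the additive Gaussian noise.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size: float = 20.0  # nm/px
    n_fibers: int = 40
    diameter_mean: float = 5.0
    diameter_sd: float = 1.0
    orientation_mu: float = 0.0
    orientation_kappa: float = 0.0
    fiber_intensity: float = 0.85
    background_intensity: float = 0.15
    blur_sigma: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.image_size) == 2, "image_size: must be a (rows, cols) pair")
        _require(min(self.image_size) >= 64, "image_size: must be at least 64x64")
        _require(self.pixel_size > 0, "pixel_size: must be positive")
        _require(self.n_fibers >= 1, "n_fibers: must be a positive integer")
        _require(self.diameter_mean > 0, "diameter_mean: must be positive")
        _require(self.diameter_sd >= 0, "diameter_sd: must be non-negative")
        _require(-90 <= self.orientation_mu < 90, "orientation_mu: must lie in [-90, 90)")
        _require(self.orientation_kappa >= 0, "orientation_kappa: must be non-negative")
        for name in ("fiber_intensity", "background_intensity"):
            v = getattr(self, name)
            _require(0 <= v <= 1, f"{name}: must lie in [0, 1]")
        _require(
            self.fiber_intensity != self.background_intensity,
            "fiber_intensity: must differ from background_intensity",
        )
        _require(self.blur_sigma >= 0, "blur_sigma: must be non-negative")
        _require(self.noise_sd >= 0, "noise_sd: must be non-negative")


@dataclass
class FiberRecord:
    """One rendered fiber: centerline endpoints (row, col), its angle in
    [-90, 90) and rendered width (px)."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    angle: float
    width: float


@dataclass
class FiberGroundTruth:
    fibers: list[FiberRecord]
    true_mask: BinaryMask
    true_porosity: float


def _sample_fiber_angles(rng: np.random.Generator, spec: FiberImageSpec) -> np.ndarray:
    """Fiber-axis angles in [-90, 90) from a doubled-angle von Mises law."""
    if spec.orientation_kappa >= 1e6:
        return np.full(spec.n_fibers, spec.orientation_mu, dtype=float)
    doubled = rng.vonmises(
        np.radians(2.0 * spec.orientation_mu), spec.orientation_kappa, size=spec.n_fibers
    )
    angles = np.degrees(doubled) / 2.0
    return ((angles + 90.0) % 180.0) - 90.0


def render_fiber_mask(
    shape: tuple[int, int],
    centers: np.ndarray,
    angles: np.ndarray,
    widths: np.ndarray,
) -> np.ndarray:
    """Digitize straight constant-width bars into a boolean mask.

    A pixel is fiber when its perpendicular distance to some centerline
    is at most ``width / 2``; even widths are centered between pixel
    rows/columns so an axis-aligned bar of integer width ``w`` occupies
    exactly ``w`` rows.
    """
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), theta, w in zip(np.atleast_2d(centers), np.atleast_1d(angles), np.atleast_1d(widths)):
        if w % 2 == 0:  # even widths center between pixel rows
            r0, c0 = r0 + 0.5, c0 + 0.5
        t = math.radians(theta)
        # direction along the fiber in (row, col); image rows grow downward
        ur, uc = -math.sin(t), math.cos(t)
        cross = (rr - r0) * uc - (cc - c0) * ur
        mask |= np.abs(cross) <= w / 2.0
    return mask


def generate_fiber_image(spec: FiberImageSpec) -> tuple[GrayscaleImage, FiberGroundTruth]:
    """Render a fibrous image and its exact pre-noise ground truth.

    Fibers are straight bars of constant width crossing the whole frame:
    a pixel belongs to a fiber when its perpendicular distance to the
    fiber centerline is at most ``width / 2``.  Centers are snapped to
    pixel rows/columns (half-integer positions for even widths) so an
    axis-aligned bar of integer width ``w`` occupies exactly ``w`` pixel
    rows; oblique bars digitize to the same width up to pixelation.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    angles = _sample_fiber_angles(rng, spec)
    widths = rng.normal(spec.diameter_mean, spec.diameter_sd, size=spec.n_fibers)
    widths = np.clip(np.round(widths), 1.0, None)
    centers = np.column_stack(
        [rng.integers(0, rows, size=spec.n_fibers), rng.integers(0, cols, size=spec.n_fibers)]
    ).astype(float)

    mask = render_fiber_mask((rows, cols), centers, angles, widths)
    fibers: list[FiberRecord] = []
    half_span = math.hypot(rows, cols)
    for (r0, c0), theta, w in zip(centers, angles, widths):
        t = math.radians(theta)
        ur, uc = -math.sin(t), math.cos(t)
        p0 = (r0 - half_span * ur, c0 - half_span * uc)
        p1 = (r0 + half_span * ur, c0 + half_span * uc)
        fibers.append(FiberRecord(endpoints=(p0, p1), angle=float(theta), width=float(w)))

    image = np.where(mask, spec.fiber_intensity, spec.background_intensity)
    if spec.blur_sigma > 0:
        image = ndi.gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    truth = FiberGroundTruth(
        fibers=fibers,
        true_mask=BinaryMask(mask, pixel_size=spec.pixel_size),
        true_porosity=float(1.0 - mask.mean()),
    )
    return GrayscaleImage(image, pixel_size=spec.pixel_size), truth


# --------------------------------------------------------------------------
# cell outlines
# --------------------------------------------------------------------------

@dataclass
class CellOutlineTruth:
    """An outline together with the analytic geometry of the ellipse it
    discretizes."""

    outline: CellOutline
    true_area: float
    true_perimeter: float
    true_major: float
    true_minor: float

    @property
    def true_aspect_ratio(self) -> float:
        return self.true_major / self.true_minor


def generate_cell_outlines(
    n_cells: int,
    elongation_mean: float = 1.0,
    seed: int = 0,
    radius_mean: float = 10.0,
    radius_sd: float = 0.0,
    elongation_sd: float = 0.0,
    n_vertices: int = 720,
) -> list[CellOutlineTruth]:
    """Closed elliptical cell outlines of controllable elongation.

    Each cell is an ellipse of effective radius ``r`` (so its area is
    ``pi * r**2`` regardless of elongation), semi-axes
    ``a = r * sqrt(e)`` and ``b = r / sqrt(e)`` with elongation
    ``e = a / b``, random orientation and center, discretized to
    ``n_vertices`` points.
    """
    _require(n_cells >= 1, "n_cells: must be at least 1")
    _require(elongation_mean >= 1, "elongation_mean: must be >= 1")
    _require(radius_mean > 0, "radius_mean: must be positive")
    _require(n_vertices >= 3, "n_vertices: must be at least 3")
    rng = np.random.default_rng(seed)
    phases = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    cells: list[CellOutlineTruth] = []
    for i in range(n_cells):
        r = max(1e-3, rng.normal(radius_mean, radius_sd)) if radius_sd > 0 else radius_mean
        e = max(1.0, rng.normal(elongation_mean, elongation_sd)) if elongation_sd > 0 else elongation_mean
        a, b = r * math.sqrt(e), r / math.sqrt(e)
        phi = rng.uniform(0.0, math.pi)
        cx, cy = rng.uniform(50.0, 950.0, size=2)
        x = a * np.cos(phases)
        y = b * np.sin(phases)
        xr = cx + x * math.cos(phi) - y * math.sin(phi)
        yr = cy + x * math.sin(phi) + y * math.cos(phi)
        # analytic ellipse perimeter via the complete elliptic integral
        perimeter = 4.0 * a * ellipe(1.0 - (b / a) ** 2)
        cells.append(
            CellOutlineTruth(
                outline=CellOutline(np.column_stack([xr, yr]), cell_id=i),
                true_area=math.pi * a * b,
                true_perimeter=float(perimeter),
                true_major=2.0 * a,
                true_minor=2.0 * b,
            )
        )
    return cells


# --------------------------------------------------------------------------
# rheology
# --------------------------------------------------------------------------

@dataclass
class MaxwellSpec:
    """Single-mode Maxwell element: plateau modulus (Pa), relaxation time
    (s), log-scale multiplicative noise, and the frequency grid (rad/s)."""

    modulus_scale: float = 100.0
    relaxation_time: float = 1.0
    noise_sd: float = 0.0
    frequency_grid: tuple[float, ...] = DEFAULT_FREQUENCY_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.modulus_scale > 0, "modulus_scale: must be positive")
        _require(self.relaxation_time > 0, "relaxation_time: must be positive")
        _require(self.noise_sd >= 0, "noise_sd: must be non-negative")
        grid = np.asarray(self.frequency_grid, dtype=float)
        _require(grid.size >= 3, "frequency_grid: must have at least 3 points")
        _require(bool(np.all(grid > 0)), "frequency_grid: must be positive")
        _require(bool(np.all(np.diff(grid) > 0)), "frequency_grid: must be strictly increasing")


def generate_rheology_sweep(spec: MaxwellSpec, label: str = "") -> RheologySweep:
    """Maxwell-model frequency sweep with optional log-normal noise."""
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.frequency_grid, dtype=float)
    wt = w * spec.relaxation_time
    g_storage = spec.modulus_scale * wt**2 / (1.0 + wt**2)
    g_loss = spec.modulus_scale * wt / (1.0 + wt**2)
    if spec.noise_sd > 0:
        g_storage = g_storage * np.exp(rng.normal(0.0, spec.noise_sd, size=w.size))
        g_loss = g_loss * np.exp(rng.normal(0.0, spec.noise_sd, size=w.size))
    return RheologySweep(w, g_storage, g_loss, label=label)


# --------------------------------------------------------------------------
# expression tables
# --------------------------------------------------------------------------

@dataclass
class ExpressionSimSpec:
    """Two-condition gene table with planted up/down protein-coding genes.

    Null genes have log-normal fold changes around 1 (sd ``null_fold_sd``
    on the log scale) and uniform raw p-values; planted genes have fold
    changes beyond ``effect_fold`` (above it for up, below its reciprocal
    for down) and small raw p-values.
    """

    n_genes: int = 2000
    biotype_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPORTIONS)
    )
    n_up: int = 50
    n_down: int = 50
    effect_fold: float = 3.0
    null_fold_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes >= 1, "n_genes: must be positive")
        _require(self.effect_fold > 1.5, "effect_fold: must exceed 1.5")
        _require(self.null_fold_sd > 0, "null_fold_sd: must be positive")
        _require(self.n_up >= 0 and self.n_down >= 0, "n_up/n_down: must be non-negative")
        total = sum(self.biotype_proportions.values())
        _require(abs(total - 1.0) <= 1e-9, "biotype_proportions: must sum to 1")
        _require(
            set(self.biotype_proportions) <= set(DEFAULT_BIOTYPE_PROPORTIONS),
            "biotype_proportions: unknown biotype key",
        )
        n_coding = self._biotype_counts()["protein_coding"]
        _require(
            self.n_up + self.n_down <= n_coding,
            "n_up: planted counts exceed the protein-coding pool",
        )

    def _biotype_counts(self) -> dict[str, int]:
        """Deterministic per-biotype counts by largest remainder."""
        items = sorted(self.biotype_proportions.items())
        raw = {k: v * self.n_genes for k, v in items}
        counts = {k: int(math.floor(v)) for k, v in raw.items()}
        short = self.n_genes - sum(counts.values())
        for k, _ in sorted(raw.items(), key=lambda kv: kv[1] - math.floor(kv[1]), reverse=True)[:short]:
            counts[k] += 1
        return counts


def generate_expression_table(spec: ExpressionSimSpec) -> pd.DataFrame:
    """Gene table with columns gene_id, biotype, fold_change, p_raw and the
    ground-truth column ``planted`` in {up, down, none}."""
    rng = np.random.default_rng(spec.seed)
    counts = spec._biotype_counts()
    biotypes = np.concatenate([np.full(c, b) for b, c in sorted(counts.items())])
    rng.shuffle(biotypes)
    n = spec.n_genes
    fold = np.exp(rng.normal(0.0, spec.null_fold_sd, size=n))
    p_raw = rng.uniform(0.0, 1.0, size=n)
    planted = np.full(n, "none", dtype=object)

    coding_idx = np.flatnonzero(biotypes == "protein_coding")
    chosen = rng.choice(coding_idx, size=spec.n_up + spec.n_down, replace=False)
    up_idx, down_idx = chosen[: spec.n_up], chosen[spec.n_up :]
    # planted effects sit at or beyond the effect fold by construction
    fold[up_idx] = spec.effect_fold * np.exp(np.abs(rng.normal(0.0, 0.15, size=spec.n_up)))
    fold[down_idx] = 1.0 / (
        spec.effect_fold * np.exp(np.abs(rng.normal(0.0, 0.15, size=spec.n_down)))
    )
    n_planted = spec.n_up + spec.n_down
    p_raw[chosen] = rng.uniform(1e-8, 1e-4, size=n_planted)
    planted[up_idx] = "up"
    planted[down_idx] = "down"

    return pd.DataFrame(
        {
            "gene_id": [f"GENE{i:05d}" for i in range(n)],
            "biotype": biotypes,
            "fold_change": fold,
            "p_raw": p_raw,
            "planted": planted,
        }
    )


# --------------------------------------------------------------------------
# cytokine arrays
# --------------------------------------------------------------------------

def generate_cytokine_array(
    n_analytes: int,
    background: float = 2.0,
    reference: float = 20.0,
    seed: int = 0,
    level_scale: float = 0.5,
    spot_noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Duplicate-spot cytokine array with background and reference spots.

    Each analyte gets two spot intensities around
    ``background + level * reference``; the recorded ``true_level`` is
    the duplicate-average-minus-background over reference normalization
    of the rendered spots (floored at 0), i.e. exactly what a correct
    normalizer should return.
    """
    _require(n_analytes >= 1, "n_analytes: must be positive")
    _require(reference > 0, "reference: must be positive")
    rng = np.random.default_rng(seed)
    levels = rng.exponential(level_scale, size=n_analytes)
    rows = []
    for i, lvl in enumerate(levels):
        signal = background + lvl * reference
        d1, d2 = signal + rng.normal(0.0, spot_noise_sd, size=2)
        true_level = max(0.0, ((d1 + d2) / 2.0 - background) / reference)
        rows.append(
            {
                "analyte": f"CYT{i:03d}",
                "spot_1": d1,
                "spot_2": d2,
                "background": background,
                "reference": reference,
                "true_level": true_level,
            }
        )
    return pd.DataFrame(rows)
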