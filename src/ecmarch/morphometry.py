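"""Cell-shape morphometry and tumor-volume calculation.

Circularity is the isoperimetric quotient ``c = 4*pi*A / P**2`` (1 for a
circle, lower for elongated or irregular shapes); aspect ratio is the
length:width ratio of the minimum-area rotated bounding rectangle, a
reproducible stand-in for calliper-style length/width measurement of a
cell outline.  Tumor volume from calliper radii uses the modified
ellipsoid formula ``V = 4/3 * pi * L * S**2`` with L the larger and S
the smaller radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

__all__ = [
    "CellOutline",
    "CellShapeRecord",
    "circularity",
    "aspect_ratio",
    "measure_cell",
    "tumor_volume",
    "compare_shape_groups",
]


@dataclass
class CellOutline:
    """A closed, non-self-intersecting polygon tracing one cell (px)."""

    vertices: np.ndarray  # (n, 2) array of (x, y)
    cell_id: int | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a cell outline needs at least 3 vertices")

    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("self-intersecting cell outline")
        return poly


@dataclass
class CellShapeRecord:
    circularity: float
    aspect_ratio: float
    area: float
    perimeter: float
    length: float
    width: float
    cell_id: int | None = None


def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric circularity ``4*pi*A / P**2``; 1 for a circle."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def aspect_ratio(length: float, width: float) -> float:
    """Length:width ratio, ordered so the result is >= 1."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return max(length, width) / min(length, width)


def measure_cell(outline: CellOutline) -> CellShapeRecord:
    """Shape descriptors of one outline.

    Area is the shoelace area, perimeter the vertex-chain Euclidean
    length, and length/width the side lengths of the minimum-area rotated
    bounding rectangle.
    """
    poly = outline.polygon()
    area = poly.area
    perimeter = poly.length
    if area <= 0:
        raise ValueError("degenerate outline with zero area")
    rect = poly.minimum_rotated_rectangle
    rx, ry = rect.exterior.coords.xy
    corners = np.column_stack([rx, ry])[:4]
    side1 = float(np.linalg.norm(corners[1] - corners[0]))
    side2 = float(np.linalg.norm(corners[2] - corners[1]))
    length, width = max(side1, side2), min(side1, side2)
    return CellShapeRecord(
        circularity=circularity(area, perimeter),
        aspect_ratio=aspect_ratio(length, width),
        area=area,
        perimeter=perimeter,
        length=length,
        width=width,
        cell_id=outline.cell_id,
    )


def tumor_volume(L: float, S: float) -> float:
    """Modified ellipsoid tumor volume ``4/3 * pi * L * S**2`` (mm^3).

    L is the larger and S the smaller calliper radius; swapped inputs are
    reordered with a warning.
    """
    if L <= 0 or S <= 0:
        raise ValueError("radii must be positive")
    if S > L:
        warnings.warn("S > L: radii reordered so L is the larger")
        L, S = S, L
    return (4.0 / 3.0) * math.pi * L * S**2


def compare_shape_groups(
    groups: list[list[CellShapeRecord]],
    metric: str = "circularity",
    welch: bool = False,
) -> dict:
    """Compare a shape metric across cell groups.

    Two groups: two-sided unpaired t-test (equal-variance by default,
    Welch with ``welch=True``).  More than two: one-way ANOVA followed by
    Tukey's HSD pairwise comparisons.
    """
    if metric not in ("circularity", "aspect_ratio", "area"):
        raise ValueError(f"unknown shape metric {metric!r}")
    samples = [np.array([getattr(r, metric) for r in g], dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for i, s in enumerate(samples):
        if s.size < 2:
            raise ValueError(f"group {i} needs n >= 2")
    if len(samples) == 2:
        t, p = stats.ttest_ind(samples[0], samples[1], equal_var=not welch)
        return {"test": "welch_t" if welch else "student_t", "statistic": float(t), "p": float(p)}
    f, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    pairwise = {
        (i, j): float(tukey.pvalue[i, j])
        for i in range(len(samples))
        for j in range(i + 1, len(samples))
    }
    return {"test": "anova_tukey", "statistic": float(f), "p": float(p), "tukey_p": pairwise}
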