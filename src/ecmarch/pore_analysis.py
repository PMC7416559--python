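"""Pore census and porosity comparison.

Pores are connected clusters of non-fiber pixels fully surrounded by
fiber: background components touching the image border are excluded
(they are open space, not enclosed pores), as are components below a
minimum detectable size, which filters small segmentation errors.
Background components use 4-connectivity and the fiber phase 8-
connectivity, the standard digital-topology pairing.

Group comparison uses Welch's unequal-variance t-test, appropriate when
the two pore populations have different sizes and spreads, with a
Bonferroni correction across the requested pore metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.measure import label, regionprops

from .segmentation import BinaryMask

__all__ = [
    "PoreRecord",
    "PorositySummary",
    "WelchResult",
    "detect_pores",
    "summarize_porosity",
    "welch_test",
    "compare_pore_groups",
    "DEFAULT_MIN_PORE_SIZE",
    "PORE_METRICS",
]

#: Default minimum detectable pore size (px^2).
DEFAULT_MIN_PORE_SIZE = 10

PORE_METRICS = ("area", "perimeter", "major_axis", "minor_axis")


@dataclass
class PoreRecord:
    """Geometry of one retained pore.

    Axes come from the component's second central moments (the
    ellipse-equivalent convention); perimeter is the outer-boundary
    pixel-edge length with diagonal correction.
    """

    id: int
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    centroid: tuple[float, float]
    touches_border: bool = False


@dataclass
class PorositySummary:
    n_pores: int
    pore_area_fraction: float
    stats: dict  # metric -> {mean, median, sd}
    group: str = ""


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    p_adjusted: float | None = None


def detect_pores(
    mask: BinaryMask,
    min_size: int = DEFAULT_MIN_PORE_SIZE,
    connectivity: int = 4,
) -> list[PoreRecord]:
    """Locate, filter and measure pores in a fiber mask.

    Connected components of non-fiber pixels are counted; components
    touching any image edge or with area below ``min_size`` are dropped.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    background = ~mask.pixels
    labeled = label(background, connectivity=1 if connectivity == 4 else 2)
    nrows, ncols = mask.shape
    pores: list[PoreRecord] = []
    for region in regionprops(labeled):
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols
        if touches or region.area < min_size:
            continue
        pores.append(
            PoreRecord(
                id=len(pores) + 1,
                area=float(region.area),
                perimeter=float(region.perimeter),
                major_axis=float(region.axis_major_length),
                minor_axis=float(region.axis_minor_length),
                centroid=tuple(float(x) for x in region.centroid),
                touches_border=False,
            )
        )
    return pores


def summarize_porosity(
    pores: list[PoreRecord], mask: BinaryMask, group: str = ""
) -> PorositySummary:
    """Group-level porosity statistics over retained pores."""
    total_px = mask.pixels.size
    pore_px = sum(p.area for p in pores)
    metric_stats: dict[str, dict] = {}
    for metric in PORE_METRICS:
        vals = np.array([getattr(p, metric) for p in pores], dtype=float)
        if vals.size:
            metric_stats[metric] = {
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            }
        else:
            metric_stats[metric] = {"mean": None, "median": None, "sd": None}
    return PorositySummary(
        n_pores=len(pores),
        pore_area_fraction=pore_px / total_px,
        stats=metric_stats,
        group=group,
    )


def welch_test(a, b) -> WelchResult:
    """Two-sided unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, x in (("a", a), ("b", b)):
        if x.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("both groups have zero variance; t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(
        t=float(t), df=float(df), p=float(p),
        mean_a=float(a.mean()), mean_b=float(b.mean()), n_a=int(na), n_b=int(nb),
    )


def compare_pore_groups(
    pores_a: list[PoreRecord],
    pores_b: list[PoreRecord],
    metrics: tuple[str, ...] = PORE_METRICS,
) -> dict[str, WelchResult]:
    """Welch's test per pore metric, Bonferroni-adjusted across metrics."""
    if not pores_a or not pores_b:
        raise ValueError("both pore groups must be non-empty")
    for m in metrics:
        if m not in PORE_METRICS:
            raise ValueError(f"unknown pore metric {m!r}")
    results: dict[str, WelchResult] = {}
    k = len(metrics)
    for m in metrics:
        res = welch_test(
            [getattr(p, m) for p in pores_a], [getattr(p, m) for p in pores_b]
        )
        res.p_adjusted = min(1.0, res.p * k)
        results[m] = res
    return results
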