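"""File I/O and pipeline configuration.

Conventions used throughout the package: pixel coordinates are
(row, col), 0-based, origin at the top-left, ranges half-open.  Images
are read from TIFF or PNG (8- or 16-bit) and rescaled to [0, 1] by the
dtype maximum on load; masks are written as 8-bit rasters with 0 =
non-fiber and 255 = fiber.  Configuration is a flat YAML or JSON mapping
validated against :class:`PipelineConfig`; unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import BinaryMask, GrayscaleImage
from .rheology import RheologySweep

__all__ = [
    "PipelineConfig",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
    "read_config",
    "read_rheology_csv",
    "config_hash",
]

RHEOLOGY_COLUMNS = ("omega_rad_s", "g_storage_pa", "g_loss_pa")


@dataclass
class PipelineConfig:
    """Parameters of the end-to-end image pipeline.

    Defaults equal the module-level defaults of each stage.
    """

    input_image: str | None = None
    output_dir: str = "ecmarch_out"
    pixel_size: float | None = None
    # segmentation
    segmentation_mode: str = "otsu"  # otsu | fixed
    fixed_threshold: float | None = None
    fibers_bright: bool = True
    contrast_low_pct: float = 1.0
    contrast_high_pct: float = 99.0
    # fiber architecture
    min_fiber_component_px: int = 10
    diameter_bin_width: float = 1.0
    # pores
    min_pore_size: int = 10
    pore_connectivity: int = 4
    # orientation
    orientation_window_sigma: float = 7.0
    centerline_dilation_px: int = 2
    orientation_bins: int = 36
    # screen thresholds
    fold_up_threshold: float = 1.5
    fold_down_threshold: float = 0.5
    alpha: float = 0.05
    # randomness
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return PipelineConfig.from_mapping(data)


def _to_unit_range(raw: np.ndarray) -> np.ndarray:
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    arr = raw.astype(float)
    if arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def read_image(path: str | Path, pixel_size: float | None = None) -> GrayscaleImage:
    """Read a TIFF/PNG micrograph, rescaling intensities to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    raw = tifffile.imread(path) if path.suffix in (".tif", ".tiff") else iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3:  # collapse RGB(A) to luminance
        raw = raw[..., :3].mean(axis=-1)
    return GrayscaleImage(_to_unit_range(raw), pixel_size=pixel_size)


def write_image(path: str | Path, image: GrayscaleImage, bit_depth: int = 16) -> None:
    """Write an image as 8- or 16-bit TIFF/PNG."""
    if bit_depth == 8:
        raster = np.round(image.pixels * 255).astype(np.uint8)
    elif bit_depth == 16:
        raster = np.round(image.pixels * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, raster)
    else:
        iio.imwrite(path, raster)


def read_mask(path: str | Path, pixel_size: float | None = None) -> BinaryMask:
    img = read_image(path, pixel_size)
    return BinaryMask(img.pixels > 0.5, pixel_size=pixel_size)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    raster = np.where(mask.pixels, 255, 0).astype(np.uint8)
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, raster)
    else:
        iio.imwrite(path, raster)


def read_table(
    path: str | Path, required_columns: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Read a CSV/TSV table, checking required columns by name."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in required_columns if c not in table.columns]
    if missing:
        raise ValueError(f"table {path} missing required column(s): {missing}")
    return table


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    sep = "\t" if Path(path).suffix in (".tsv", ".tab") else ","
    table.to_csv(path, sep=sep, index=False)


def read_rheology_csv(path: str | Path, label: str = "") -> RheologySweep:
    """Read a frequency sweep (omega_rad_s, g_storage_pa, g_loss_pa)."""
    table = read_table(path, required_columns=RHEOLOGY_COLUMNS)
    return RheologySweep(
        table["omega_rad_s"].to_numpy(),
        table["g_storage_pa"].to_numpy(),
        table["g_loss_pa"].to_numpy(),
        label=label,
    )
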