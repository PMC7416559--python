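"""End-to-end matrix-architecture pipeline.

Chains the imaging stages — contrast adjustment, segmentation,
centerline/diameter estimation, pore census, orientation analysis — and
writes every stage's outputs plus a manifest (package version, config
hash, seed, per-stage files) for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import fiber_architecture as fa
from . import orientation_analysis as oa
from . import pore_analysis as pa
from . import segmentation as seg
from .io import (
    PipelineConfig,
    config_hash,
    read_image,
    write_mask,
    write_table,
)

__all__ = ["run_pipeline"]

log = logging.getLogger("ecmarch")


def run_pipeline(config: PipelineConfig, image: seg.GrayscaleImage | None = None) -> dict:
    """Run segment -> fibers -> pores -> orientation on one image.

    ``image`` may be supplied in memory; otherwise ``config.input_image``
    is read.  Returns the manifest (also written to the output directory).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if image is None:
        if config.input_image is None:
            raise ValueError("no input image: set config.input_image or pass one")
        image = read_image(config.input_image, pixel_size=config.pixel_size)
    manifest: dict = {
        "package": "ecmarch",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def _stage(name: str):
        log.info("stage %s: starting", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        # --- segmentation ------------------------------------------------
        st = _stage("segment")
        adjusted = seg.adjust_contrast(
            image, config.contrast_low_pct, config.contrast_high_pct
        )
        mask = seg.threshold_segment(
            adjusted,
            method=config.segmentation_mode,
            fixed_value=config.fixed_threshold,
            fibers_bright=config.fibers_bright,
        )
        write_mask(out / "mask.png", mask)
        st["mask"] = "mask.png"
        st["fiber_fraction"] = mask.fiber_fraction

        # --- fiber diameters ---------------------------------------------
        st = _stage("fibers")
        skeleton = fa.skeletonize(mask, config.min_fiber_component_px)
        dmap = fa.distance_transform(mask)
        dist = fa.estimate_fiber_diameters(mask, skeleton, dmap)
        diam_table = pd.DataFrame(
            {
                "row": dist.coords[:, 0],
                "col": dist.coords[:, 1],
                "diameter_px": dist.diameters_px,
            }
        )
        if dist.diameters_nm is not None:
            diam_table["diameter_nm"] = dist.diameters_nm
        write_table(out / "fiber_diameters.csv", diam_table)
        st["diameters"] = "fiber_diameters.csv"
        st["summary"] = dist.summary()

        # --- pores ---------------------------------------------------------
        st = _stage("pores")
        pores = pa.detect_pores(mask, config.min_pore_size, config.pore_connectivity)
        pore_table = pd.DataFrame([dataclasses.asdict(p) for p in pores])
        write_table(out / "pores.csv", pore_table)
        summary = pa.summarize_porosity(pores, mask)
        st["pores"] = "pores.csv"
        st["n_pores"] = summary.n_pores
        st["pore_area_fraction"] = summary.pore_area_fraction

        # --- orientation ----------------------------------------------------
        st = _stage("orient")
        field = oa.structure_tensor_field(adjusted, config.orientation_window_sigma)
        angles = oa.centerline_orientations(field, skeleton, config.centerline_dilation_px)
        if angles.size:
            distn = oa.orientation_distribution(angles, config.orientation_bins)
            score = oa.alignment_score(angles)
            write_table(
                out / "orientation_distribution.csv",
                pd.DataFrame(
                    {"bin_center_deg": distn.bin_centers, "weight": distn.weights}
                ),
            )
            st["distribution"] = "orientation_distribution.csv"
            st["alignment_score"] = score.S
            st["n_samples"] = score.n_samples
            st["peak_angles_deg"] = distn.peak_angles
        else:
            st["alignment_score"] = None
            st["n_samples"] = 0
    except Exception as exc:
        # keep partial outputs; record where the pipeline halted
        manifest["failed_stage"] = list(manifest["stages"])[-1] if manifest["stages"] else None
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
        raise RuntimeError(
            f"pipeline halted in stage {manifest['failed_stage']!r}: {exc}"
        ) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
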