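"""Orchestration of the fibrosis-quantification stage sequence, batch
execution, overlay rendering, and spreadsheet export.

Per image the stages run in this order:

1.  unmix hematoxylin (secondary PAS) to highlight tubule rims;
2.  Gaussian smoothing;
3.  identify tubule objects (size-filtered, holes filled so lumina join
    their rims);
4.  invert the smoothed tubule image (kept as an intermediate);
5.  mask the original image with the inverted tubule mask -> tubule-less
    image;
6.  convert to grayscale;
7.  optionally mask out user-supplied ROI polygons;
8.  identify bright non-fibrotic areas (pale interstitium, intratubular
    space) and mask them out;
9.  unmix methyl blue (secondary ponceau-fuchsin) on the remaining pixels;
10. invert the transmission rendering -> collagen signal;
11. threshold the signal on the remaining valid pixels and measure the
    fibrotic area fraction over the full frame.

Batch execution writes one CSV row per image with the area-occupied and
total-area column names used by the original spreadsheet export, so percent
fibrosis can always be recomputed downstream as 100 * area / total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import objects as obj
from . import quantify, raster_core, unmix
from .objects import ObjectFilter, ThresholdSpec
from .raster_core import BinaryMask, RGBImage, ROISet, ValidityMask

__all__ = [
    "PipelineConfig",
    "FibrosisResult",
    "run_pipeline",
    "run_batch",
    "overlay_objects",
    "AREA_COLUMN",
    "TOTAL_COLUMN",
]

logger = logging.getLogger("fibroquant")

#: Spreadsheet column names for the fibrosis area measurement, kept
#: compatible with the original export so downstream sheets keep working.
AREA_COLUMN = "AreaOccupied_AreaOccupied_ThresholdFibrosis"
TOTAL_COLUMN = "AreaOccupied_TotalArea_ThresholdFibrosis"

CSV_COLUMNS = [
    "image_id",
    AREA_COLUMN,
    TOTAL_COLUMN,
    "percent_fibrosis",
    "fibrosis_threshold_used",
    "n_tubules",
    "n_interstitium_objects",
    "status",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the stage sequence, with calibration defaults.

    The structure-detection thresholds carry informative bounds: tubule rims
    are the most strongly hematoxylin-dense structures (lower bound 0.8 on
    the unmixed signal) and the interstitium stage only removes bright,
    clearly non-fibrotic pixels (lower bound 0.75 on grayscale). The bounds
    keep Otsu's adaptive choice inside a physically sensible band; they are
    the settings to retune for differently stained image lots.
    """

    unmix_tubules: tuple[str, str] = ("hematoxylin", "pas")
    smooth_sigma: float = 1.0
    tubule_filter: ObjectFilter = field(
        default_factory=lambda: ObjectFilter(
            min_diameter=20.0, max_diameter=400.0, connectivity=8,
            keep_border=True, fill_holes=True,
        )
    )
    tubule_threshold: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec(
            method="otsu", correction_factor=1.0, lower_bound=0.8, upper_bound=0.95,
        )
    )
    interstitium_filter: ObjectFilter = field(
        default_factory=lambda: ObjectFilter(
            min_diameter=3.0, max_diameter=float("inf"), connectivity=8,
            keep_border=True, fill_holes=False,
        )
    )
    interstitium_threshold: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec(
            method="otsu", correction_factor=1.0, lower_bound=0.75, upper_bound=1.0,
        )
    )
    unmix_fibrosis: tuple[str, str] = ("methyl_blue", "ponceau_fuchsin")
    fibrosis_threshold: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec(
            method="otsu", correction_factor=1.0, lower_bound=0.05, upper_bound=0.95,
        )
    )
    gray_weights: tuple[float, float, float] = (0.299, 0.587, 0.114)
    stains: Mapping[str, Sequence[float]] = field(default_factory=dict)
    roi_dir: Optional[Path] = None
    save_intermediates: bool = False
    output_dir: Path = Path("fibroquant_output")

    # -- construction from config files ------------------------------------

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls()

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("unmix_tubules", "unmix_fibrosis", "gray_weights"):
            if key in data:
                kwargs[key] = tuple(data[key])
        for key in ("smooth_sigma", "save_intermediates"):
            if key in data:
                kwargs[key] = data[key]
        for key in ("tubule_filter", "interstitium_filter"):
            if key in data:
                kwargs[key] = ObjectFilter(**data[key])
        for key in ("tubule_threshold", "interstitium_threshold", "fibrosis_threshold"):
            if key in data:
                kwargs[key] = ThresholdSpec(**data[key])
        if "stains" in data:
            kwargs["stains"] = dict(data["stains"])
        if data.get("roi_dir") is not None:
            kwargs["roi_dir"] = Path(data["roi_dir"])
        if "output_dir" in data:
            kwargs["output_dir"] = Path(data["output_dir"])
        unknown = set(data) - {
            "unmix_tubules", "unmix_fibrosis", "gray_weights", "smooth_sigma",
            "save_intermediates", "tubule_filter", "interstitium_filter",
            "tubule_threshold", "interstitium_threshold", "fibrosis_threshold",
            "stains", "roi_dir", "output_dir",
        }
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})


@dataclass(frozen=True)
class FibrosisResult:
    """One image's measurement plus the exclusion-stage bookkeeping."""

    image_id: str
    measurement: quantify.AreaMeasurement
    fibrosis_threshold_used: float
    n_tubules: int
    n_interstitium_objects: int
    n_fibrosis_objects: int = 0
    fibrosis_mask: Optional[BinaryMask] = None
    intermediate_paths: tuple = ()


def run_pipeline(
    img: RGBImage,
    cfg: Optional[PipelineConfig] = None,
    rois: Optional[ROISet] = None,
    image_id: str = "image",
) -> FibrosisResult:
    """Execute the full stage sequence on one image."""
    if cfg is None:
        cfg = PipelineConfig.default()
    lib = unmix.stain_library(cfg.stains)
    validity = ValidityMask.full(img.shape)

    # (1-3) tubule identification on the smoothed hematoxylin signal
    c_hema = unmix.unmix_colors(
        img, lib[cfg.unmix_tubules[0]], lib[cfg.unmix_tubules[1]]
    )
    tubule_signal = unmix.concentration_to_signal(c_hema)
    smoothed = obj.smooth_gaussian(tubule_signal, cfg.smooth_sigma, validity)
    tubules = obj.identify_primary_objects(
        smoothed, cfg.tubule_filter, cfg.tubule_threshold, validity
    )
    logger.info("%s: %d tubule objects", image_id, tubules.n_objects)

    # (4) inverted tubule image, kept for inspection
    inverted_tubules = raster_core.image_math("invert", smoothed)

    # (5) remove tubules from the original image
    tubule_mask = obj.objects_to_mask(tubules)
    masked_rgb, validity = raster_core.mask_image(
        img, tubule_mask, invert_mask=True, validity=validity
    )

    # (6) grayscale conversion
    gray = raster_core.color_to_gray(masked_rgb, cfg.gray_weights)

    # (7) manual ROI exclusions
    if rois is not None and len(rois) > 0:
        roi_mask = raster_core.rasterize_rois(rois, img.height, img.width)
        gray, validity = raster_core.mask_image(
            gray, roi_mask, invert_mask=True, validity=validity
        )

    # (8) remove bright non-fibrotic areas (pale interstitium, lumina)
    interstitium = obj.identify_primary_objects(
        gray, cfg.interstitium_filter, cfg.interstitium_threshold, validity
    )
    _, validity = raster_core.mask_image(
        gray, obj.objects_to_mask(interstitium), invert_mask=True, validity=validity
    )
    logger.info("%s: %d interstitium objects", image_id, interstitium.n_objects)

    # (9-10) collagen signal from the remaining pixels
    remaining_rgb, _ = raster_core.mask_image(
        img, BinaryMask(validity.pixels), invert_mask=False, validity=validity
    )
    c_collagen = unmix.unmix_colors(
        remaining_rgb, lib[cfg.unmix_fibrosis[0]], lib[cfg.unmix_fibrosis[1]]
    )
    transmission = unmix.concentration_to_transmission(c_collagen)
    collagen_signal = raster_core.image_math("invert", transmission)

    # (11) threshold and measure
    measurement, t_used, fibrosis_mask = quantify.measure_fibrosis(
        collagen_signal, cfg.fibrosis_threshold, validity
    )
    fibrosis_objects = obj.label_components(
        fibrosis_mask, cfg.interstitium_filter.connectivity
    )
    logger.info(
        "%s: threshold %.4f, %.2f%% fibrosis", image_id, t_used, measurement.percent
    )

    intermediate_paths: tuple = ()
    if cfg.save_intermediates:
        inter_dir = Path(cfg.output_dir) / "intermediates"
        inter_dir.mkdir(parents=True, exist_ok=True)
        saved = []
        for name, raster in [
            ("tubule_signal", smoothed),
            ("inverted_tubules", inverted_tubules),
            ("tubule_mask", tubule_mask),
            ("gray_tubule_less", gray),
            ("collagen_signal", collagen_signal),
            ("fibrosis_mask", fibrosis_mask),
        ]:
            p = inter_dir / f"{image_id}_{name}.png"
            raster_core.write_image(p, raster)
            saved.append(p)
        intermediate_paths = tuple(saved)

    return FibrosisResult(
        image_id=image_id,
        measurement=measurement,
        fibrosis_threshold_used=t_used,
        n_tubules=tubules.n_objects,
        n_interstitium_objects=interstitium.n_objects,
        n_fibrosis_objects=fibrosis_objects.n_objects,
        fibrosis_mask=fibrosis_mask,
        intermediate_paths=intermediate_paths,
    )


def overlay_objects(
    img: RGBImage,
    mask: BinaryMask,
    color: Sequence[float] = (1.0, 0.0, 0.0),
    alpha: float = 0.5,
) -> RGBImage:
    """Alpha-blend ``color`` over the foreground pixels of ``mask``."""
    if mask.shape != img.shape:
        raise ValueError("mask shape does not match image")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    col = np.asarray(color, dtype=float)
    if col.shape != (3,) or col.min() < 0 or col.max() > 1:
        raise ValueError("color must be an RGB triple in [0, 1]")
    blended = alpha * col[None, None, :] + (1.0 - alpha) * img.pixels
    out = np.where(mask.pixels[:, :, None], blended, img.pixels)
    return RGBImage(out)


def _result_row(result: FibrosisResult) -> dict:
    m = result.measurement
    return {
        "image_id": result.image_id,
        AREA_COLUMN: m.area_occupied,
        TOTAL_COLUMN: m.total_area,
        "percent_fibrosis": m.percent,
        "fibrosis_threshold_used": result.fibrosis_threshold_used,
        "n_tubules": result.n_tubules,
        "n_interstitium_objects": result.n_interstitium_objects,
        "status": "ok",
    }


def run_batch(
    input_paths: Sequence[Path | str],
    cfg: Optional[PipelineConfig] = None,
    write_overlays: bool = False,
) -> pd.DataFrame:
    """Process every image independently and export one CSV row per image.

    Failed images are logged and flagged (``status='failed'``), never
    silently dropped. Rows are ordered by image_id, so the output is
    invariant to the input ordering; the CSV is written to
    ``<output_dir>/fibrosis_results.csv``.
    """
    if not input_paths:
        raise ValueError("run_batch needs at least one input path")
    if cfg is None:
        cfg = PipelineConfig.default()
    out_dir = Path(cfg.output_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    rows = []
    for path in input_paths:
        path = Path(path)
        image_id = path.stem
        try:
            img = raster_core.read_image(path)
            rois = None
            if cfg.roi_dir is not None:
                roi_path = Path(cfg.roi_dir) / f"{image_id}.roi"
                if roi_path.exists():
                    rois = raster_core.read_roi_file(roi_path)
            result = run_pipeline(img, cfg, rois, image_id=image_id)
            rows.append(_result_row(result))
            if write_overlays and result.fibrosis_mask is not None:
                overlay = overlay_objects(img, result.fibrosis_mask)
                raster_core.write_image(out_dir / f"{image_id}_overlay.png", overlay)
        except Exception as exc:
            logger.error("%s: failed: %s", image_id, exc)
            rows.append(
                {
                    "image_id": image_id,
                    AREA_COLUMN: np.nan,
                    TOTAL_COLUMN: np.nan,
                    "percent_fibrosis": np.nan,
                    "fibrosis_threshold_used": np.nan,
                    "n_tubules": np.nan,
                    "n_interstitium_objects": np.nan,
                    "status": "failed",
                }
            )
    table = pd.DataFrame(rows, columns=CSV_COLUMNS).sort_values(
        "image_id", kind="stable", ignore_index=True
    )
    table.to_csv(out_dir / "fibrosis_results.csv", index=False)
    return table
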