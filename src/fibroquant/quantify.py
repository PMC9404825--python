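"""Area-fraction morphometry: area-occupied accounting, the percent-fibrosis
formula, and a reference single-channel measurement for cross-validation.

The headline quantity is::

    %fibrosis = (area occupied by fibrosis / total area) * 100

where the total area is always the full frame (H * W): structures that were
excluded from analysis (tubules, manual ROIs) still dilute the percentage,
exactly as when the exported area-occupied and total-area columns are
divided downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .objects import ThresholdSpec, apply_threshold, compute_threshold
from .raster_core import BinaryMask, GrayImage, RGBImage, ValidityMask

__all__ = [
    "AreaMeasurement",
    "ReferenceSpec",
    "measure_area_occupied",
    "percent_fibrosis",
    "measure_fibrosis",
    "reference_measure",
]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class AreaMeasurement:
    """Foreground pixel count, frame pixel count, and their percentage."""

    area_occupied: int
    total_area: int
    percent: float

    def __post_init__(self) -> None:
        if not (0 <= self.area_occupied <= self.total_area):
            raise ValueError("need 0 <= area_occupied <= total_area")
        expected = 100.0 * self.area_occupied / self.total_area
        if abs(self.percent - expected) > 1e-9:
            raise ValueError("percent inconsistent with area_occupied/total_area")


@dataclass(frozen=True)
class ReferenceSpec:
    """Single-channel banded threshold (the ImageJ-style cross-check).

    Pixels whose value in the selected channel lies in the closed interval
    ``[min_threshold, max_threshold]`` count as fibrotic.
    """

    channel: str = "green"
    min_threshold: float = 0.0
    max_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {sorted(_CHANNELS)}")
        if not (0.0 <= self.min_threshold <= self.max_threshold <= 1.0):
            raise ValueError("need 0 <= min_threshold <= max_threshold <= 1")


def percent_fibrosis(area_occupied: int, total_area: int) -> float:
    """``100 * area_occupied / total_area``."""
    if total_area <= 0:
        raise ZeroDivisionError("total_area must be > 0")
    if not (0 <= area_occupied <= total_area):
        raise ValueError("need 0 <= area_occupied <= total_area")
    return 100.0 * area_occupied / total_area


def measure_area_occupied(mask: BinaryMask) -> AreaMeasurement:
    """Count foreground pixels of a thresholded binary image against the
    full frame (the MeasureImageAreaOccupied stage)."""
    occupied = mask.count()
    total = mask.pixels.size
    return AreaMeasurement(occupied, total, percent_fibrosis(occupied, total))


def measure_fibrosis(
    img: GrayImage,
    spec: ThresholdSpec,
    validity: Optional[ValidityMask] = None,
) -> tuple[AreaMeasurement, float, BinaryMask]:
    """Threshold the collagen-signal image on its valid pixels and measure
    the resulting fibrotic area.

    Returns the measurement, the threshold actually used (after correction
    factor and bounds), and the binary fibrosis mask.
    """
    t = compute_threshold(img, spec, validity)
    mask = apply_threshold(img, t, validity)
    return measure_area_occupied(mask), t, mask


def reference_measure(img: RGBImage, spec: ReferenceSpec) -> AreaMeasurement:
    """Banded single-channel threshold measurement over the full frame,
    emulating the min/max-threshold procedure of general-purpose image
    software; used only as an internal cross-check of the pipeline."""
    channel = img.pixels[:, :, _CHANNELS[spec.channel]]
    selected = (channel >= spec.min_threshold) & (channel <= spec.max_threshold)
    return measure_area_occupied(BinaryMask(selected))
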