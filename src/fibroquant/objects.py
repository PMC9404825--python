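"""Structure detection: Gaussian smoothing, threshold selection on unmasked
pixels, and primary-object identification with equivalent-diameter filtering.

These stages mirror the Smooth / Threshold / IdentifyPrimaryObjects steps of
the fibrosis workflow. Objects are formed from thresholded foreground by
connected-component labeling (4- or 8-connectivity), then filtered by their
equivalent-circle diameter ``d = 2 * sqrt(area / pi)``. Declumping of
touching objects is deliberately not implemented: the workflow only uses
objects to build exclusion masks, for which merged objects are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure

from .raster_core import BinaryMask, GrayImage, ValidityMask

__all__ = [
    "ThresholdSpec",
    "ObjectFilter",
    "LabelMap",
    "smooth_gaussian",
    "compute_threshold",
    "apply_threshold",
    "label_components",
    "identify_primary_objects",
    "objects_to_mask",
    "measure_objects",
]

#: Number of histogram bins used for Otsu threshold selection, regardless of
#: the input bit depth.
OTSU_BINS = 256


@dataclass(frozen=True)
class ThresholdSpec:
    """How a foreground/background threshold is chosen.

    ``method='otsu'`` minimizes weighted intra-class variance on a 256-bin
    histogram of the *valid* pixels; ``method='fixed'`` uses ``fixed_value``.
    The computed value is multiplied by ``correction_factor`` and clamped to
    ``[lower_bound, upper_bound]``.
    """

    method: str = "otsu"
    correction_factor: float = 1.0
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    fixed_value: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if not self.correction_factor > 0:
            raise ValueError("correction_factor must be > 0")
        if not (0.0 <= self.lower_bound <= self.upper_bound <= 1.0):
            raise ValueError("threshold bounds must satisfy 0 <= lower <= upper <= 1")
        if not (0.0 <= self.fixed_value <= 1.0):
            raise ValueError("fixed_value must lie in [0, 1]")


@dataclass(frozen=True)
class ObjectFilter:
    """Size/connectivity criteria for identified objects.

    Diameters are equivalent-circle diameters in pixels. Border-touching
    objects are kept by default: a structure partially in frame must still be
    excluded from the fibrosis area. ``fill_holes`` closes enclosed holes
    (e.g. tubule lumina inside a stained rim) before filtering.
    """

    min_diameter: float = 1.0
    max_diameter: float = float("inf")
    connectivity: int = 8
    keep_border: bool = True
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_diameter <= self.max_diameter):
            raise ValueError("need 0 < min_diameter <= max_diameter")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class LabelMap:
    """H x W nonnegative integer labels; 0 = background, objects 1..n."""

    pixels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or not np.issubdtype(px.dtype, np.integer):
            raise ValueError("LabelMap requires an HxW integer array")
        if px.size and px.min() < 0:
            raise ValueError("labels must be >= 0")
        present = np.unique(px[px > 0])
        expected = np.arange(1, self.n_objects + 1)
        if not np.array_equal(present, expected):
            raise ValueError("labels must be exactly {1..n_objects}")
        object.__setattr__(self, "pixels", px.astype(np.int32))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _skimage_connectivity(connectivity: int) -> int:
    return 1 if connectivity == 4 else 2


def smooth_gaussian(
    img: GrayImage, sigma: float, validity: Optional[ValidityMask] = None
) -> GrayImage:
    """Mask-aware Gaussian smoothing with reflective boundaries.

    Invalid pixels neither contribute to nor receive smoothed intensity
    (normalized convolution); they are returned as 0.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    px = img.pixels
    if validity is None or validity.pixels.all():
        out = ndi.gaussian_filter(px, sigma=sigma, mode="reflect")
        return GrayImage(np.clip(out, 0.0, 1.0))
    v = validity.pixels.astype(float)
    num = ndi.gaussian_filter(px * v, sigma=sigma, mode="reflect")
    den = ndi.gaussian_filter(v, sigma=sigma, mode="reflect")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    out = np.where(validity.pixels, out, 0.0)
    return GrayImage(np.clip(out, 0.0, 1.0))


def _otsu_histogram_threshold(values: np.ndarray) -> float:
    """Bin-edge threshold minimizing weighted intra-class variance.

    Candidate thresholds are the 256 left bin edges k/256 (k = 0..255) of a
    histogram over [0, 1]; bin centers stand in for the pixel values. Ties in
    the objective are broken toward the lowest threshold. A constant input
    returns that constant.
    """
    if values.min() == values.max():
        return float(values.min())
    hist, edges = np.histogram(values, bins=OTSU_BINS, range=(0.0, 1.0))
    p = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = p.sum()

    cum_w = np.cumsum(p)
    cum_s = np.cumsum(p * centers)
    cum_q = np.cumsum(p * centers**2)
    # split at edge k: class 0 = bins < k, class 1 = bins >= k, for k = 0..255
    w0 = np.concatenate([[0.0], cum_w[:-1]])
    s0 = np.concatenate([[0.0], cum_s[:-1]])
    q0 = np.concatenate([[0.0], cum_q[:-1]])
    w1 = total - w0
    s1 = cum_s[-1] - s0
    q1 = cum_q[-1] - q0

    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = np.where(w0 > 0, q0 / w0 - (s0 / w0) ** 2, 0.0)
        var1 = np.where(w1 > 0, q1 / w1 - (s1 / w1) ** 2, 0.0)
    objective = (w0 * np.maximum(var0, 0.0) + w1 * np.maximum(var1, 0.0)) / total
    k = int(np.argmin(objective))  # argmin takes the first (lowest) on ties
    return float(edges[k])


def compute_threshold(
    img: GrayImage, spec: ThresholdSpec, validity: Optional[ValidityMask] = None
) -> float:
    """Threshold value computed from the valid (unmasked) pixels only, then
    scaled by the correction factor and clamped to the spec's bounds."""
    if validity is None:
        values = img.pixels.ravel()
    else:
        if validity.shape != img.shape:
            raise ValueError("validity shape does not match image")
        values = img.pixels[validity.pixels]
    if values.size == 0:
        raise ValueError("cannot compute a threshold with zero valid pixels")
    if spec.method == "fixed":
        t = spec.fixed_value
    else:
        t = _otsu_histogram_threshold(values)
    t *= spec.correction_factor
    return float(min(max(t, spec.lower_bound), spec.upper_bound))


def apply_threshold(
    img: GrayImage, t: float, validity: Optional[ValidityMask] = None
) -> BinaryMask:
    """Foreground = valid pixels strictly above ``t``; invalid pixels are
    always background."""
    if not (0.0 <= t <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    fg = img.pixels > t
    if validity is not None:
        fg &= validity.pixels
    return BinaryMask(fg)


def label_components(mask: BinaryMask, connectivity: int = 8) -> LabelMap:
    """Connected-component labeling; labels assigned 1..N in raster-scan
    order of each component's first pixel."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    raw = skmeasure.label(
        mask.pixels, connectivity=_skimage_connectivity(connectivity), background=0
    )
    return _relabel_raster_order(raw)


def _relabel_raster_order(raw: np.ndarray) -> LabelMap:
    flat = raw.ravel()
    fg = np.flatnonzero(flat)
    if fg.size == 0:
        return LabelMap(np.zeros(raw.shape, dtype=np.int32), 0)
    labels = flat[fg]
    # order labels by first occurrence in raster scan
    first_idx = np.full(labels.max() + 1, flat.size, dtype=np.int64)
    np.minimum.at(first_idx, labels, fg)
    present = np.flatnonzero(first_idx < flat.size)
    order = present[np.argsort(first_idx[present], kind="stable")]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return LabelMap(remap[raw], int(order.size))


def identify_primary_objects(
    img: GrayImage,
    obj_filter: ObjectFilter,
    spec: ThresholdSpec,
    validity: Optional[ValidityMask] = None,
) -> LabelMap:
    """Threshold, label, and size-filter bright structures (the
    IdentifyPrimaryObjects stage).

    Objects whose equivalent-circle diameter falls outside
    ``[min_diameter, max_diameter]`` are discarded, as are border-touching
    objects when ``keep_border`` is false; survivors are relabeled
    contiguously from 1 in raster-scan order.
    """
    t = compute_threshold(img, spec, validity)
    fg = apply_threshold(img, t, validity).pixels
    if obj_filter.fill_holes and fg.any():
        fg = ndi.binary_fill_holes(fg)
    labels = label_components(BinaryMask(fg), obj_filter.connectivity)
    if labels.n_objects == 0:
        return labels
    px = labels.pixels
    areas = np.bincount(px.ravel(), minlength=labels.n_objects + 1)[1:]
    diameters = 2.0 * np.sqrt(areas / np.pi)
    keep = (diameters >= obj_filter.min_diameter) & (diameters <= obj_filter.max_diameter)
    if not obj_filter.keep_border:
        border_labels = np.unique(
            np.concatenate([px[0, :], px[-1, :], px[:, 0], px[:, -1]])
        )
        keep[border_labels[border_labels > 0] - 1] = False
    remap = np.zeros(labels.n_objects + 1, dtype=np.int32)
    remap[1:][keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return LabelMap(remap[px], int(keep.sum()))


def objects_to_mask(labels: LabelMap) -> BinaryMask:
    """Binary footprint of all objects (label > 0)."""
    return BinaryMask(labels.pixels > 0)


def measure_objects(labels: LabelMap) -> pd.DataFrame:
    """Per-object area, centroid and equivalent-circle diameter.

    Returns a DataFrame with columns ``label``, ``area``, ``centroid_row``,
    ``centroid_col``, ``equivalent_diameter``; one row per object.
    """
    cols = ["label", "area", "centroid_row", "centroid_col", "equivalent_diameter"]
    if labels.n_objects == 0:
        return pd.DataFrame(columns=cols)
    props = skmeasure.regionprops_table(
        labels.pixels, properties=("label", "area", "centroid", "equivalent_diameter")
    )
    df = pd.DataFrame(props).rename(
        columns={
            "centroid-0": "centroid_row",
            "centroid-1": "centroid_col",
            "equivalent_diameter": "equivalent_diameter",
        }
    )
    df = df[cols].sort_values("label", ignore_index=True)
    df["area"] = df["area"].astype(int)
    return df
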