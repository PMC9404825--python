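"""Raster carriers and pixel-level plumbing shared by every pipeline stage.

Conventions used throughout the package:

* images are ``float64`` arrays with intensities in ``[0, 1]``;
* the origin is the top-left corner, ``x`` indexes columns and ``y`` rows,
  both 0-based, and the center of pixel ``(row, col)`` sits at
  ``(x, y) = (col + 0.5, row + 0.5)``;
* masking never silently discards information: every masking stage zeroes
  the dropped pixels *and* records them in a :class:`ValidityMask`, so that
  downstream statistics (threshold selection in particular) can be
  restricted to the pixels that still carry signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RGBImage",
    "GrayImage",
    "BinaryMask",
    "ValidityMask",
    "ROISet",
    "read_image",
    "write_image",
    "color_to_gray",
    "image_math",
    "mask_image",
    "rasterize_rois",
    "read_roi_file",
]


class FormatError(ValueError):
    """Raised for rasters or ROI files that do not match the expected layout."""


def _check_unit_range(pixels: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(pixels)):
        raise ValueError(f"{what}: non-finite pixel values")
    if pixels.size and (pixels.min() < 0.0 or pixels.max() > 1.0):
        raise ValueError(f"{what}: pixel values outside [0, 1]")


@dataclass(frozen=True)
class RGBImage:
    """H x W x 3 real-valued image with channel intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"RGBImage requires an HxWx3 array, got shape {px.shape}")
        _check_unit_range(px, "RGBImage")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class GrayImage:
    """H x W real-valued image with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"GrayImage requires an HxW array, got shape {px.shape}")
        _check_unit_range(px, "GrayImage")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """H x W boolean mask; True marks selected/foreground pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2:
            raise FormatError(f"BinaryMask requires an HxW array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ValidityMask:
    """H x W booleans; True means the pixel still participates in statistics.

    Starts all-true and is intersected (logical AND) at each masking stage.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2:
            raise FormatError(f"ValidityMask requires an HxW array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ValidityMask":
        return cls(np.ones(shape, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ROISet:
    """Named exclusion polygons in pixel coordinates (x = column, y = row)."""

    polygons: tuple = ()
    names: tuple = ()

    def __post_init__(self) -> None:
        polys = []
        for p in self.polygons:
            arr = np.asarray(p, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise FormatError("each ROI polygon needs >= 3 (x, y) vertices")
            polys.append(arr)
        object.__setattr__(self, "polygons", tuple(polys))
        names = tuple(self.names) if self.names else tuple(
            f"roi_{i}" for i in range(len(polys))
        )
        if len(names) != len(polys):
            raise FormatError("ROISet names and polygons differ in length")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.polygons)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path: Union[str, Path]) -> RGBImage:
    """Read a raster file (JPG/PNG/TIFF/BMP) into a normalized :class:`RGBImage`.

    Integer samples are divided by the maximum representable value for their
    bit depth (255 for 8-bit, 65535 for 16-bit). Single-channel inputs are
    replicated to three channels; an alpha channel is dropped.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    arr = np.asarray(raw)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[2] not in (1, 3, 4):
        raise FormatError(
            f"{path}: unsupported channel count (shape {arr.shape}); expected 1, 3 or 4"
        )
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)

    if np.issubdtype(arr.dtype, np.integer):
        maxval = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(float) / maxval
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    return RGBImage(arr)


def write_image(path: Union[str, Path], img: Union[RGBImage, GrayImage, BinaryMask]) -> None:
    """Write an image as 8-bit PNG/BMP or 16-bit TIFF depending on extension."""
    path = Path(path)
    if isinstance(img, BinaryMask):
        px = img.pixels.astype(float)
    else:
        px = img.pixels
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        out = np.round(px * 65535.0).astype(np.uint16)
    else:
        out = np.round(px * 255.0).astype(np.uint8)
    iio.imwrite(path, out)


# ---------------------------------------------------------------------------
# Pixelwise operations
# ---------------------------------------------------------------------------

def color_to_gray(img: RGBImage, weights: Sequence[float]) -> GrayImage:
    """Weighted-channel grayscale conversion (the ColorToGray stage)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must be three numbers")
    if np.any(w < 0):
        raise ValueError("channel weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("channel weights must sum to a positive value")
    w = w / total
    gray = np.tensordot(img.pixels, w, axes=([2], [0]))
    return GrayImage(np.clip(gray, 0.0, 1.0))


def image_math(
    op: str,
    a: GrayImage,
    b: Union[GrayImage, float, None] = None,
    clamp: bool = True,
) -> GrayImage:
    """Pixelwise arithmetic (the ImageMath stage).

    ``invert`` computes ``1 - a``; the binary ops combine ``a`` with an image
    or scalar ``b``. With ``clamp`` the result is clipped to [0, 1];
    divide-by-zero pixels map to 0.
    """
    pa = a.pixels
    if op == "invert":
        out = 1.0 - pa
    else:
        if b is None:
            raise ValueError(f"image_math '{op}' needs a second operand")
        pb = b.pixels if isinstance(b, GrayImage) else float(b)
        if isinstance(pb, np.ndarray) and pb.shape != pa.shape:
            raise ValueError(f"operand shapes differ: {pa.shape} vs {pb.shape}")
        if op == "add":
            out = pa + pb
        elif op == "subtract":
            out = pa - pb
        elif op == "multiply":
            out = pa * pb
        elif op == "divide":
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(np.asarray(pb) == 0.0, 0.0, pa / pb)
        else:
            raise ValueError(f"unknown image_math op {op!r}")
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return GrayImage(out)


def mask_image(
    img: Union[RGBImage, GrayImage],
    mask: BinaryMask,
    invert_mask: bool = False,
    validity: ValidityMask | None = None,
):
    """Zero out pixels deselected by ``mask`` and track them as invalid.

    A pixel is retained where ``mask XOR invert_mask`` is true; everywhere
    else it is set to 0 and marked invalid in the returned
    :class:`ValidityMask` (AND-combined with the incoming validity).
    """
    if mask.shape != img.pixels.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {img.pixels.shape[:2]}")
    keep = mask.pixels ^ bool(invert_mask)
    if validity is None:
        validity = ValidityMask.full(mask.shape)
    elif validity.shape != mask.shape:
        raise ValueError("validity shape does not match image")
    new_validity = ValidityMask(validity.pixels & keep)
    if isinstance(img, RGBImage):
        out = np.where(keep[:, :, None], img.pixels, 0.0)
        return RGBImage(out), new_validity
    out = np.where(keep, img.pixels, 0.0)
    return GrayImage(out), new_validity


# ---------------------------------------------------------------------------
# ROI handling
# ---------------------------------------------------------------------------

def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, half-open on edges."""
    inside = np.zeros(px.shape, dtype=bool)
    n = poly.shape[0]
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        crosses = (y0 <= py) != (y1 <= py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_rois(rois: ROISet, height: int, width: int) -> BinaryMask:
    """Rasterize ROI polygons: a pixel is selected iff its center (col + 0.5,
    row + 0.5) lies inside any polygon under the even-odd rule. Vertices may
    lie outside the frame; the raster is implicitly clipped to it.
    """
    if height < 1 or width < 1:
        raise ValueError("frame dimensions must be >= 1")
    mask = np.zeros((height, width), dtype=bool)
    if len(rois) == 0:
        return BinaryMask(mask)
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    px = cols + 0.5
    py = rows + 0.5
    for poly in rois.polygons:
        mask |= _points_in_polygon(px, py, poly)
    return BinaryMask(mask)


def read_roi_file(path: Union[str, Path]) -> ROISet:
    """Parse a plain-text ROI file.

    Format: one polygon per block; a block starts with a name line (any text
    without a comma or second token), followed by one ``x y`` or ``x,y``
    vertex per line; blank lines and ``#`` comments are ignored.
    """
    path = Path(path)
    names: list[str] = []
    polys: list[list[tuple[float, float]]] = []
    current: list[tuple[float, float]] | None = None
    for line in path.read_text().splitlines():
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        tokens = text.replace(",", " ").split()
        if len(tokens) == 2:
            try:
                x, y = float(tokens[0]), float(tokens[1])
            except ValueError:
                pass
            else:
                if current is None:
                    names.append(f"roi_{len(polys)}")
                    current = []
                    polys.append(current)
                current.append((x, y))
                continue
        # anything else starts a new named polygon
        names.append(text)
        current = []
        polys.append(current)
    for name, poly in zip(names, polys):
        if len(poly) < 3:
            raise FormatError(f"{path}: polygon {name!r} has fewer than 3 vertices")
    return ROISet(tuple(np.asarray(p) for p in polys), tuple(names))
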