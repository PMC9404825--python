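"""Beer-Lambert stain model: absorbance vectors, color deconvolution, and
forward compositing.

Under the Beer-Lambert law, the transmitted intensity of channel ``c`` at a
pixel carrying stains ``s`` with concentrations ``a_s`` is

    I_c = I0_c * 10 ** (-sum_s a_s * q_{s,c})

where ``q_s`` is the stain's unit-norm absorbance (optical density) vector.
Optical densities are additive across stains, so a pixel's OD vector
``-log10(I / I0)`` is a nonnegative combination of the stain vectors, and
per-stain concentrations can be recovered by per-pixel least squares
(standard color deconvolution). Concentrations are expressed in OD units
along the stain's unit vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .raster_core import GrayImage, RGBImage

__all__ = [
    "StainVector",
    "ODImage",
    "ConcentrationMap",
    "stain_library",
    "od_transform",
    "unmix_colors",
    "composite_stains",
    "concentration_to_transmission",
    "concentration_to_signal",
    "DEFAULT_EPS",
]

#: One quantization step below the darkest 8-bit level; caps OD at ~2.408.
DEFAULT_EPS = 1.0 / 256.0


@dataclass(frozen=True)
class StainVector:
    """Named unit-norm triple of per-channel absorbances for one dye."""

    name: str
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.absorbance, dtype=float)
        if vec.shape != (3,):
            raise ValueError(f"stain {self.name!r}: absorbance must have 3 components")
        if np.any(vec < 0) or not np.all(np.isfinite(vec)):
            raise ValueError(f"stain {self.name!r}: absorbances must be finite and >= 0")
        norm = float(np.linalg.norm(vec))
        if norm <= 0:
            raise ValueError(f"stain {self.name!r}: at least one component must be > 0")
        object.__setattr__(self, "absorbance", vec / norm)

    @classmethod
    def from_raw(cls, name: str, rgb_od: Sequence[float]) -> "StainVector":
        return cls(name, np.asarray(rgb_od, dtype=float))


@dataclass(frozen=True)
class ODImage:
    """H x W x 3 optical densities (absorbance per channel)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"ODImage requires HxWx3, got {px.shape}")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("ODImage values must be finite and >= 0")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ConcentrationMap:
    """H x W per-stain concentration in OD units along the stain vector."""

    pixels: np.ndarray
    stain: Optional[StainVector] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"ConcentrationMap requires HxW, got {px.shape}")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("concentrations must be finite and >= 0")
        object.__setattr__(self, "pixels", px)


# Default absorbance triples (R, G, B optical densities, normalized on
# construction). Hematoxylin and PAS follow the published color-deconvolution
# values in wide use; methyl blue is modelled as a blue-transmitting anionic
# dye (smallest blue absorbance) and ponceau-fuchsin as a red-transmitting
# counterstain (smallest red absorbance). All overridable via configuration.
_DEFAULT_STAINS: dict[str, tuple[float, float, float]] = {
    "hematoxylin": (0.650, 0.704, 0.286),
    "pas": (0.175, 0.972, 0.155),
    "methyl_blue": (0.800, 0.560, 0.120),
    "ponceau_fuchsin": (0.100, 0.740, 0.670),
}


def stain_library(
    overrides: Optional[Mapping[str, Sequence[float]]] = None,
) -> dict[str, StainVector]:
    """Return the named stain vectors, optionally overridden/extended.

    Always contains ``hematoxylin``, ``pas``, ``methyl_blue`` and
    ``ponceau_fuchsin``; each entry is unit-norm.
    """
    lib = {name: StainVector.from_raw(name, od) for name, od in _DEFAULT_STAINS.items()}
    if overrides:
        for name, od in overrides.items():
            lib[name] = StainVector.from_raw(name, od)
    return lib


def get_stain(library: Mapping[str, StainVector], name: str) -> StainVector:
    try:
        return library[name]
    except KeyError:
        raise KeyError(
            f"unknown stain {name!r}; available: {sorted(library)}"
        ) from None


def od_transform(img: RGBImage, eps: float = DEFAULT_EPS) -> ODImage:
    """Per-channel absorbance ``OD = -log10(max(I, eps))`` against a white
    reference; white maps to zero OD and values are capped at ``-log10(eps)``.
    """
    if not (0.0 < eps < 1.0):
        raise ValueError("eps must lie in (0, 1)")
    od = -np.log10(np.maximum(img.pixels, eps))
    return ODImage(np.maximum(od, 0.0))


def unmix_colors(
    img: RGBImage,
    primary: StainVector,
    secondary: Optional[StainVector] = None,
    eps: float = DEFAULT_EPS,
) -> ConcentrationMap:
    """Recover the primary stain's concentration map (the UnmixColors stage).

    Each pixel's OD vector is decomposed by ordinary least squares onto the
    primary (and, if given, secondary) stain direction; the primary
    coefficient, floored at zero, is returned. Residual absorbance orthogonal
    to the stain pair is ignored.
    """
    od = od_transform(img, eps).pixels.reshape(-1, 3)
    p = primary.absorbance
    if secondary is None:
        coeff = od @ p  # unit norm: projection = OLS coefficient
    else:
        s = secondary.absorbance
        cosang = float(np.dot(p, s))
        if 1.0 - abs(cosang) < 1e-9:
            raise ValueError(
                f"stains {primary.name!r} and {secondary.name!r} are collinear; "
                "cannot unmix"
            )
        basis = np.stack([p, s], axis=1)  # 3 x 2
        # closed-form OLS via the normal equations (2x2 system)
        gram_inv = np.linalg.inv(basis.T @ basis)
        coeff = (od @ basis @ gram_inv)[:, 0]
    coeff = np.maximum(coeff, 0.0)
    return ConcentrationMap(coeff.reshape(img.shape), primary)


def composite_stains(
    maps: Sequence[tuple[ConcentrationMap, StainVector]],
    background: Sequence[float] = (1.0, 1.0, 1.0),
    shape: Optional[tuple[int, int]] = None,
) -> RGBImage:
    """Forward Beer-Lambert compositing of stain concentration fields.

    ``I_c = background_c * 10 ** (-sum_s map_s * absorbance_{s,c})``, clipped
    to [0, 1]. The inverse of :func:`unmix_colors` on clean images.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (3,) or np.any(bg <= 0) or np.any(bg > 1):
        raise ValueError("background channels must lie in (0, 1]")
    if not maps:
        if shape is None:
            raise ValueError("composite_stains needs maps or an explicit shape")
        return RGBImage(np.broadcast_to(bg, (*shape, 3)).copy())
    base_shape = maps[0][0].pixels.shape
    for cmap, _ in maps:
        if cmap.pixels.shape != base_shape:
            raise ValueError("all concentration maps must share one shape")
    total_od = np.zeros((*base_shape, 3))
    for cmap, vec in maps:
        total_od += cmap.pixels[:, :, None] * vec.absorbance[None, None, :]
    rgb = bg[None, None, :] * np.power(10.0, -total_od)
    return RGBImage(np.clip(rgb, 0.0, 1.0))


def concentration_to_transmission(cmap: ConcentrationMap) -> GrayImage:
    """Render a concentration map as transmitted intensity ``10**(-c)``.

    Stain-rich pixels appear dark, matching how an unmixed single-stain image
    looks under the microscope; inverting this rendering (the ImageMath
    stage) yields the stain signal used for thresholding.
    """
    return GrayImage(np.power(10.0, -cmap.pixels))


def concentration_to_signal(cmap: ConcentrationMap) -> GrayImage:
    """Render a concentration map as absorbed fraction ``1 - 10**(-c)``
    (stain-rich pixels bright); equals inverting the transmission rendering.
    """
    return GrayImage(1.0 - np.power(10.0, -cmap.pixels))
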