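"""Synthetic Masson's-trichrome kidney photomicrographs with ground truth.

The generator renders the three tissue classes the fibrosis workflow must
tell apart, composited through the same Beer-Lambert stain model the
unmixing stage inverts:

* **tubules** — non-overlapping ellipses with a hematoxylin-dense rim
  annulus and a pale lumen;
* **fibrosis** — ramified blob-shaped methyl-blue (collagen) patches grown
  in the extratubular space until their pixel count first reaches the
  requested area fraction of the frame;
* **interstitium** — everything else, carrying the ponceau-fuchsin red
  counterstain.

Gaussian camera noise is added in RGB transmission space after compositing.
The returned ground-truth masks are mutually exclusive, so every stage of
the pipeline (tubule exclusion, interstitium masking, collagen thresholding)
can be scored against known truth without any external image data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .raster_core import BinaryMask, RGBImage, write_image
from .unmix import ConcentrationMap, StainVector, composite_stains, stain_library

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PlacementError",
    "generate_synthetic_kidney",
    "generate_fixture_suite",
    "write_fixture_suite",
]


class PlacementError(RuntimeError):
    """Raised when the requested geometry cannot be placed in the frame."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one synthetic photomicrograph.

    Stain levels are optical densities along the stain's unit absorbance
    vector; the defaults emulate a well-stained trichrome section captured
    at the study's canonical 1024 x 768 frame.
    """

    height: int = 768
    width: int = 1024
    n_tubules: int = 12
    tubule_diameter_range: tuple[float, float] = (60.0, 120.0)
    tubule_rim_hematoxylin: float = 1.0
    lumen_brightness: float = 0.9
    counterstain_level: float = 0.35
    fibrosis_target_fraction: float = 0.30
    fibrosis_methyl_blue: float = 0.55
    n_fibrosis_patches: int = 12
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be >= 1")
        if not (0.0 <= self.fibrosis_target_fraction < 1.0):
            raise ValueError("fibrosis_target_fraction must lie in [0, 1)")
        lo, hi = self.tubule_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("tubule_diameter_range must be ordered and positive")
        for name in ("tubule_rim_hematoxylin", "counterstain_level", "fibrosis_methyl_blue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.lumen_brightness <= 1.0):
            raise ValueError("lumen_brightness must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_tubules < 0 or self.n_fibrosis_patches < 1:
            raise ValueError("n_tubules >= 0 and n_fibrosis_patches >= 1 required")


@dataclass(frozen=True)
class GroundTruth:
    """Mutually exclusive tissue masks plus the realized fibrotic fraction."""

    tubule_mask: BinaryMask
    interstitium_mask: BinaryMask
    fibrosis_mask: BinaryMask
    true_fraction: float


# Neutral gray absorber used to dim tubule lumina slightly below white.
_NEUTRAL = StainVector("neutral_gray", np.ones(3))


def _place_tubules(spec: SyntheticSpec, rng: np.random.Generator):
    """Place non-overlapping ellipses; returns (rim_mask, lumen_mask)."""
    H, W = spec.height, spec.width
    rows, cols = np.mgrid[0:H, 0:W]
    rim = np.zeros((H, W), bool)
    lumen = np.zeros((H, W), bool)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding radius)
    lo, hi = spec.tubule_diameter_range
    max_tries = 200
    for _ in range(spec.n_tubules):
        for attempt in range(max_tries):
            d = rng.uniform(lo, hi)
            a = d / 2.0  # semi-major
            b = a * rng.uniform(0.7, 1.0)  # semi-minor
            theta = rng.uniform(0.0, np.pi)
            cy = rng.uniform(a, H - a)
            cx = rng.uniform(a, W - a)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (a + pr + 2.0) ** 2
                   for py, px, pr in placed):
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_tubules} non-overlapping tubules of "
                f"diameter {lo}-{hi} in a {H}x{W} frame after {max_tries} tries"
            )
        placed.append((cy, cx, a))
        dy, dx = rows - cy, cols - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        outer = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        rim_frac = 0.25  # rim thickness as a fraction of the radius
        inner = (u / (a * (1 - rim_frac))) ** 2 + (v / (b * (1 - rim_frac))) ** 2 <= 1.0
        rim |= outer & ~inner
        lumen |= inner
    return rim, lumen


def _grow_fibrosis(
    allowed: np.ndarray, target: int, n_patches: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow blob patches from random seeds by stochastic dilation until the
    foreground pixel count first reaches ``target`` exactly."""
    mask = np.zeros(allowed.shape, bool)
    if target == 0:
        return mask
    allowed_idx = np.flatnonzero(allowed)
    if allowed_idx.size < target:
        raise PlacementError(
            f"extratubular space ({allowed_idx.size} px) cannot hold the "
            f"requested fibrotic area ({target} px)"
        )
    seeds = rng.choice(allowed_idx, size=min(n_patches, target), replace=False)
    mask.ravel()[seeds] = True
    structure = np.ones((3, 3), bool)
    while mask.sum() < target:
        ring = ndi.binary_dilation(mask, structure) & allowed & ~mask
        ring_idx = np.flatnonzero(ring)
        if ring_idx.size == 0:
            # stuck: reseed anywhere still allowed
            free = np.flatnonzero(allowed & ~mask)
            extra = rng.choice(free, size=1)
            mask.ravel()[extra] = True
            continue
        accept = ring_idx[rng.random(ring_idx.size) < 0.65]
        if accept.size == 0:
            continue
        deficit = target - int(mask.sum())
        if accept.size > deficit:
            accept = rng.choice(accept, size=deficit, replace=False)
        mask.ravel()[accept] = True
    return mask


def generate_synthetic_kidney(spec: SyntheticSpec) -> tuple[RGBImage, GroundTruth]:
    """Render one synthetic trichrome field and its ground truth.

    Identical spec (including seed) always yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width

    rim, lumen = _place_tubules(spec, rng)
    tubule = rim | lumen

    # keep a small margin so fibrosis never abuts a tubule rim
    forbidden = ndi.binary_dilation(tubule, np.ones((3, 3), bool), iterations=2)
    target = int(round(spec.fibrosis_target_fraction * H * W))
    fibrosis = _grow_fibrosis(~forbidden, target, spec.n_fibrosis_patches, rng)

    interstitium = ~tubule & ~fibrosis

    lib = stain_library()
    hema = np.where(rim, spec.tubule_rim_hematoxylin, 0.0)
    pon = np.where(interstitium, spec.counterstain_level, 0.0)
    mb = np.where(fibrosis, spec.fibrosis_methyl_blue, 0.0)
    # lumen: neutral absorber dimming white down to lumen_brightness
    lumen_od = -np.log10(spec.lumen_brightness) * np.sqrt(3.0)
    neutral = np.where(lumen, lumen_od, 0.0)

    img = composite_stains(
        [
            (ConcentrationMap(hema), lib["hematoxylin"]),
            (ConcentrationMap(pon), lib["ponceau_fuchsin"]),
            (ConcentrationMap(mb), lib["methyl_blue"]),
            (ConcentrationMap(neutral), _NEUTRAL),
        ],
        background=(1.0, 1.0, 1.0),
    )
    pixels = img.pixels
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, pixels.shape)
        pixels = np.clip(pixels, 0.0, 1.0)

    truth = GroundTruth(
        tubule_mask=BinaryMask(tubule),
        interstitium_mask=BinaryMask(interstitium),
        fibrosis_mask=BinaryMask(fibrosis),
        true_fraction=float(fibrosis.sum()) / (H * W),
    )
    return RGBImage(pixels), truth


def generate_fixture_suite(
    fractions: Sequence[float],
    n_per_fraction: int,
    base_spec: Optional[SyntheticSpec] = None,
    seed: int = 0,
) -> list[tuple[RGBImage, GroundTruth, SyntheticSpec]]:
    """Deterministic suite spanning the requested fibrotic fractions.

    Per-image seeds are derived from the master seed, so the suite is
    reproducible element-wise and no two images coincide.
    """
    if base_spec is None:
        base_spec = SyntheticSpec()
    for f in fractions:
        if not (0.0 <= f < 1.0):
            raise ValueError("fractions must lie in [0, 1)")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(fractions) * n_per_fraction
    ) % (2**31)
    suite = []
    i = 0
    for fraction in fractions:
        for _ in range(n_per_fraction):
            spec = dataclasses.replace(
                base_spec,
                fibrosis_target_fraction=float(fraction),
                seed=int(child_seeds[i]),
            )
            img, truth = generate_synthetic_kidney(spec)
            suite.append((img, truth, spec))
            i += 1
    return suite


def write_fixture_suite(
    suite: Sequence[tuple[RGBImage, GroundTruth, SyntheticSpec]],
    out_dir: Path | str,
) -> list[Path]:
    """Write suite images as PNGs plus a ``truth.csv`` ground-truth table,
    laid out the way batch execution expects its inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    records = []
    for i, (img, truth, spec) in enumerate(suite):
        name = f"synthetic_{i:03d}.png"
        write_image(out_dir / name, img)
        paths.append(out_dir / name)
        records.append(
            {
                "image_id": f"synthetic_{i:03d}",
                "true_fraction": truth.true_fraction,
                "target_fraction": spec.fibrosis_target_fraction,
                "seed": spec.seed,
            }
        )
    pd.DataFrame(records).to_csv(out_dir / "truth.csv", index=False)
    return paths
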