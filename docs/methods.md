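# Methods

## Stain model

All raster math happens on float images in [0, 1]. The optical-density
transform is `OD_c = −log10(max(I_c, eps))` with `eps = 1/256` (one
quantization step below the darkest 8-bit level), capping OD at
`−log10(eps) ≈ 2.408`. White (1, 1, 1) has zero OD.

Each dye is a unit-norm absorbance vector (R, G, B optical densities per
unit concentration). Shipped defaults:

| stain            | raw (R, G, B) OD | note |
|------------------|------------------|------|
| hematoxylin      | 0.650, 0.704, 0.286 | published color-deconvolution value |
| pas              | 0.175, 0.972, 0.155 | published color-deconvolution value |
| methyl_blue      | 0.800, 0.560, 0.120 | blue-transmitting anionic collagen dye |
| ponceau_fuchsin  | 0.100, 0.740, 0.670 | red-transmitting cytoplasm counterstain |

No published vectors exist for the trichrome pair used here, so the methyl
blue and ponceau-fuchsin entries encode the defining property of each dye
(smallest absorbance in its own transmission band); all four are
overridable per config (`stains:` mapping).

Unmixing solves, per pixel, ordinary least squares of the OD vector on the
span of the primary (and optional secondary) stain vector via the 2×2
normal equations, then floors the primary coefficient at zero. No iterative
NNLS: the closed form matches standard color-deconvolution practice and is
exact on clean composites (round-trip error ~1e-14 in the acceptance
report). Stain pairs closer than ~1e-9 in `1 − |cosθ|` are rejected as
collinear. Concentration maps are rendered for thresholding either as
transmission `10^(−c)` (stain-dark, how a single-stain image looks) or as
signal `1 − 10^(−c)` (stain-bright); inverting the former yields the
latter, which is how the fibrosis branch's explicit inversion stage is
realized.

## Stage sequence

1. Unmix hematoxylin (secondary: PAS) → tubule-rim signal.
2. Gaussian smooth (σ = 1 px, mask-aware normalized convolution,
   reflective boundaries).
3. Identify tubule objects: Otsu threshold with bounds [0.80, 0.95],
   8-connectivity, equivalent diameter 20–400 px, holes filled so lumina
   join their rims, border objects kept (a tubule half in frame must still
   be excluded).
4. Invert the smoothed tubule image (intermediate for inspection).
5. Mask tubules out of the original image; masked pixels are zeroed *and*
   recorded in a validity mask so they never enter later statistics.
6. Grayscale conversion (weights 0.299, 0.587, 0.114).
7. Optional ROI exclusion from `<image-stem>.roi` polygon files (even-odd
   rasterization at pixel centers `col + 0.5, row + 0.5`).
8. Identify bright non-fibrotic areas (pale interstitium, intratubular
   space): Otsu with bounds [0.75, 1.0], holes *not* filled (enclosed
   collagen must survive), and mask them out.
9. Unmix methyl blue (secondary: ponceau-fuchsin) on the remaining pixels.
10. Invert the transmission rendering → collagen signal.
11. Otsu threshold (bounds [0.05, 0.95]) on the remaining valid pixels;
    count foreground; `percent = 100 · area / (H·W)`. The full frame stays
    the denominator so that excluded structures dilute the percentage.

### Why the structure stages carry tight threshold bounds

In the hematoxylin/PAS basis, methyl blue projects substantially onto the
hematoxylin direction (both absorb red strongly), so an unbounded Otsu
threshold on the tubule signal can claim collagen patches as tubules and
silently delete them from the measurement. The bounds encode a physical
prior — tubule rims are the *most* hematoxylin-dense structures in frame
(signal ≥ 0.8), and only clearly bright pixels are non-fibrotic (gray
≥ 0.75) — keeping Otsu's adaptation inside a sensible band. These, and the
threshold correction factors, are the settings to retune first for
differently stained image lots.

## Thresholding conventions

Otsu operates on a fixed 256-bin histogram of the valid pixels over [0, 1]
regardless of input bit depth; candidate thresholds are the 256 left bin
edges `k/256`; bin centers stand in for pixel values; ties in the
intra-class-variance objective break toward the lowest edge. A constant
valid region returns that constant, and since foreground is *strictly*
above the threshold, a featureless field yields no objects. The computed
value is multiplied by the correction factor, then clamped to
`[lower_bound, upper_bound]`. Fixed-value specs follow the same
correction/clamp path.

## Reference (cross-check) mode

`reference_measure` emulates the widely used general-purpose alternative:
take one channel (default green), count pixels inside a closed
`[min, max]` band, divide by the frame. It exists purely as an internal
cross-check; the agreement run in the acceptance report uses a band edge
of 0.52, the midpoint between the expected green transmission of the
generator's collagen (`10^(−0.55·0.569) ≈ 0.49`) and counterstain
(`10^(−0.35·0.738) ≈ 0.55`). The literature describes this cross-check
both as color-deconvolution plugin use and as green-channel min/max
thresholding; the channel-band reading is implemented, and the package
takes no position on which variant produced any externally reported
number.

## Synthetic generator

`SyntheticSpec` defaults render a 1024 × 768 frame (the canonical capture
size for 200× photomicrographs in this workflow): 12 non-overlapping
elliptical tubules of outer diameter 60–120 px (axis ratio 0.7–1) with a
hematoxylin rim annulus (25% of the radius, OD 1.0) and a pale lumen
(neutral absorber dimming white to 0.9); collagen patches grown from 12
random seeds by stochastic binary dilation (acceptance probability 0.65
per ring pixel) in the extratubular space — a vectorized equivalent of
random-walk blob growth producing ramified shapes — stopped exactly when
the pixel count reaches `fraction · H · W`; remaining pixels carry
ponceau-fuchsin at OD 0.35; collagen carries methyl blue at OD 0.55.
Gaussian camera noise (sd 0.01) is added in RGB transmission space after
compositing and clipped. One `numpy` Generator seeded from `spec.seed`
drives every draw, so identical specs give bit-identical images; suites
derive per-image seeds from a master `SeedSequence`.

The stain ODs sit where the pipeline's discriminations are *tight by
construction*: collagen's hematoxylin-basis projection (≈0.67 OD → signal
0.79) falls just below the tubule-stage lower bound, as real collagen is
less chromatin-dense than nuclear rims. Noise-free, single-class regions
are piecewise constant — the generator does not emulate stain gradients,
uneven illumination, JPEG artifacts, out-of-focus blur, glomeruli, or
vessels. Passing the recovery suite therefore shows the *mechanics* of the
stage sequence are correct and self-consistent, not that the default
calibration transfers to any particular real image lot; per-lot retuning
is expected, exactly as with the interactive workflow this package
automates.

Test and acceptance suites run at 512 × 384 with 8 tubules of diameter
30–60 px — the same morphology at half scale — keeping the 20-image
recovery and agreement suites at ~15 s total; the full-size default is
exercised in the unit tests and CLI example.

## Numerical and degenerate-input choices

- Masked pixels are zeroed *and* tracked in a `ValidityMask`; thresholds,
  smoothing and object statistics consume only valid pixels. Masking twice
  equals masking with the AND of the masks.
- Division by zero in `image_math` maps to 0; out-of-range results without
  clamping fail the output image's range invariant rather than passing
  silently.
- Smoothing uses normalized (mask-aware) convolution, so invalid pixels
  neither leak intensity into valid neighbors nor receive any.
- Object labels are always renumbered 1..N in raster-scan order of each
  component's first pixel, making label maps reproducible across labeling
  backends.
- An image whose valid region vanishes entirely (e.g. a full-frame ROI
  exclusion) raises, and batch execution flags that image `failed` in its
  CSV row rather than dropping or zero-filling it.
- Declumping of touching objects is deliberately omitted: merged tubules
  produce the same exclusion mask. Per-object measures beyond area,
  centroid and equivalent diameter are out of scope, as are whole-slide
  pyramidal formats and any GUI.

## Known limitations

Like the workflow it automates, the measurement cannot distinguish
physiological collagen (basement membranes) from pathological fibrosis;
with trichrome staining alone, the percent reported includes both.
Glomeruli are not specially handled — on real images they are excluded via
the ROI mechanism or by the bright-structure stage if pale enough.
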