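# Methods

This note documents the model behind `phenopipe`, the choices made where
the design was genuinely open, and what the synthetic test bed does and
does not demonstrate.

## The analysis model

`phenopipe` analyses colour photographs of individual potted plants taken
from two fixed camera perspectives — top view and side view — as produced
by automated greenhouse phenotyping platforms (or by a manual tripod
setup against a unicolour backdrop). The analysis of one image proceeds
in five stages:

1. **Region definition.** The scene furniture (pot carrier, support
   cages, sticks; in top view also the soil surface and a conveyor-belt
   strip) occupies fixed parts of the frame because the cameras do not
   move. Each such object class is bound to a named rectangle or circle
   in pixel coordinates. Regions can be rescaled collectively about
   their centroids by a single `region_scale` factor to track camera
   zoom changes. The plant carries no region: leaves may reach anywhere.
2. **Colour segmentation (MHT).** Each pixel is classified by
   multidimensional histogram thresholding: a class is a box in the
   six-channel space R, G, B (8-bit integers) × H, S, V (hue in degrees,
   saturation and value in [0, 1]), i.e. one closed `[lo, hi]` interval
   per channel, tested conjunctively. RGB and HSV are combined because
   the HSV hexcone separates chromatic identity from brightness —
   robust to illumination drift — but hue is numerically unstable at
   low saturation, where the raw RGB intervals take over. A class may
   own several boxes (disjunction) for disjoint colour modes. Classes
   are tested in declaration order; the first match whose region
   contains the pixel wins; unmatched pixels are `background`.
   Classification is strictly per-pixel: no neighbourhood context.
3. **Plant extraction.** The binary plant mask is the set of pixels
   labelled `plant`.
4. **Morphological opening.** Erosion followed by dilation with a square
   structuring element of half-width `opening_radius` (default 1, i.e.
   3×3) removes misclassified specks smaller than the element while
   preserving the plant silhouette. Pixels outside the frame count as
   background during erosion.
5. **Measurement.** From the cleaned mask: x-extent and y-extent (top
   view) or width and height (side view) as inclusive bounding-box
   extents (`max − min + 1` pixels; a single pixel is one pixel wide);
   the plant *diameter* (top view) as the maximum Feret diameter — the
   largest Euclidean distance between any two plant-pixel centres; and
   the projected shoot area, `pixel count × mm_per_px²`, in both views.
   Pixel quantities are converted to millimetres with the calibrated
   `mm_per_px` factor. Images whose mask is empty are flagged, with all
   measures zero.

Group summaries report, per group (e.g. cultivar × watering condition)
and time point, the arithmetic mean of projected shoot area and its
standard error, SE = s/√n with the sample (n−1) standard deviation.
Cells with one replicate report SE = 0 with a warning; empty cells are
omitted with a warning.

## Calibration

Threshold boxes are estimated from labelled sample pixels: per channel
the `trim` and `1 − trim` quantiles of the sample (`trim = 0`, the
default, gives the exact min/max; small positive values shed mislabelled
outliers). Hue is treated circularly: the interval is placed on the cut
that minimises the circular span of the sample — found via the largest
gap between sorted hues — and may wrap through 0° (`lo > hi` with
`wraps: true` denotes `[lo, 360) ∪ [0, hi]`). Configurations persist as
one YAML document per view with a mandatory `schema: 1` field; hue may
be given in degrees or as 8-bit values via `hue_unit: byte`
(rescaled by 360/256 on load). `validate_config` reports — as
diagnostics, not exceptions — unresolved region references, overlapping
colour volumes between classes sharing a region, zero-area regions and
non-positive `mm_per_px`.

## Fixed conventions

Several conventions are under-determined by the problem and are fixed
here so every behaviour is bit-exact and testable:

- Hue is stored in degrees `[0, 360)`; achromatic pixels (s = 0) get
  h = 0 and hue thresholds are evaluated against that value.
- All channel intervals are closed; pixels exactly on a bound match.
- Class priority is declaration order, first match wins; the plant is
  conventionally declared last among colour classes, so region-bound
  furniture classes pre-empt plant-like colours inside their regions.
- A pixel is inside a region iff its integer centre coordinate satisfies
  the closed region inequality; regions scale about their centroids and
  are clipped to the frame at rasterization.
- The structuring element is the (2r+1)×(2r+1) square.
- The maximum Feret diameter is computed via the convex hull of the
  plant-pixel centres followed by the pairwise maximum over hull
  vertices (hull vertex counts are tiny, so the quadratic step over
  vertices is exact and fast); collinear point sets fall back to the
  projection extremes. Tests verify equality with the all-pairs oracle
  to 1e-9.
- Measurements are taken after the opening.
- Annotation: the outline is the set of plant pixels with a false (or
  out-of-frame) 4-neighbour; the scale bar (default 100 mm) is
  `round(scale_bar_mm / mm_per_px)` pixels long, inset 10 px from the
  bottom-right corner, clipped with a warning if wider than the image.
- The result table has a fixed column order; lengths are written with
  two decimals (mm) and areas with one (mm²), so a rerun over identical
  inputs is byte-identical.

## The synthetic test bed

There is no deposited image set, so the `synthetic` module generates
scenes with exact ground truth. A scene is a flat light-blue backdrop
plus flat-coloured furniture objects drawn inside their regions and a
plant drawn last: a canopy rectangle on an optional stem (side view) or
a rosette ellipse with optional radial arms (top view). Each class is
painted in an interior colour of its threshold box in the companion
configuration; those boxes are derived by enumerating the full cube of
colours within the profile amplitude (default ±6 per channel) of the
palette colour, so any noise of amplitude ≤ 6 provably keeps every pixel
inside its class volume ("safe" noise). Palette colours differ by at
least 58 in some RGB channel, keeping the volumes disjoint. Noise is
uniform integer per-channel perturbation with clipping to [0, 255].

The drawn plant silhouette is regularised at generation time by one
opening at the companion configuration's radius: the true plant simply
has no features thinner than the structuring element, which makes the
pipeline's own opening idempotent on it and lets safe-noise scenes be
recovered exactly. Ground-truth extents, pixel counts and diameters are
computed by independent generation-side code (exhaustive scans and a
chunked all-pairs distance), never by the measurement module under test.

Adversarial scenes add plant-green distractor blobs inside the cages
region; their companion configuration gives the cages class a second
colour box equal to the plant's, so the region-bound class claims them
— the mechanism that, on real images, keeps green-tinted furniture and
reflections out of the plant mask.

The growth-experiment generator mirrors a two-cultivar ("Barke",
"Morex") × two-condition (well-watered, drought) screening: side-view
scenes whose canopy area is drawn log-normally around a per-group,
per-day mean. Defaults, chosen once as realistic for a barley screening
at 1 mm/px: first-day means 1400 px² ("Barke", a tillering semi-dwarf)
and 2000 px² ("Morex", taller with broader leaves), exponential growth
×1.32 per imaging interval over five time points (days 29–53 after
sowing), drought multipliers (1.0, 0.85, 0.72, 0.72, 0.85) — stress
onset after the first imaging day with partial late recovery — a
coefficient of variation of 0.20 between plants, and 8 plants per group
(matching the validation-set size used in two-view batches). Images are
192×240 px so a full batch stays cheap; the recovery properties are
size-independent as long as the canopy fits the layout.

**What passing tests do and do not show.** Flat colours with bounded
uniform noise make threshold coverage provable, so the synthetic tests
verify the *machinery* — classification, region logic, morphology,
measurement, bookkeeping — exactly. They do not show that any particular
threshold calibration separates real plants from real backgrounds:
real scenes have gradients, shadows, specular reflections and
yellow/brown senescent leaf parts whose hues overlap the soil's. With
the conventional calibration approach those tones are left out of the
plant class, which biases real-world extents slightly low at leaf tips;
that trade-off is inherited by any configuration a user derives, not
solved by the package.

## Numerical and degenerate-input choices

- `derive_profile` uses linear-interpolation quantiles, so widening the
  trim never widens an interval; an empty sample is an error.
- Empty masks: extents (0, 0), diameter 0, area 0, `empty_flag` set.
  Single-pixel masks have diameter 0.
- Region geometry may extend beyond the frame (after scaling up);
  rasterization clips, and fully outside means an all-false mask.
- Opening with radius 0 is the identity.
- Batch processing never aborts on a bad image: failures are collected
  per job and reported; the exit status of `phenopipe analyse` is
  non-zero if any job failed.
- All randomness in the synthetic module flows from a single
  `numpy.random.default_rng` seed; identical spec + seed gives
  byte-identical images.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` size their simulations to
desk scale: oracle-equivalence checks use 64×64 random images and 32×32
masks against longhand per-pixel oracles; recovery checks use 40–50
generated side-view scenes; the batch check uses the 8-plant × 6-day ×
2-view (96-image) design with a full rerun for byte-identity; and the
growth-recovery check runs 50–100 seeded replicate experiments of the
default 4-group × 8-plant × 5-day design, asking the summarised mean to
fall within 3 SE of the generator's true mean in ≥ 95% of group/day
cells.

## Known limitations

- Only the visible spectrum is handled; near-infrared and ultraviolet
  channels, conveyor/RFID metadata, watering and weighing data are out
  of scope.
- Regions are rectangles and circles; polygonal regions are not
  supported.
- Segmentation is per-pixel only; no connected components, clustering
  or learned models. Plants whose colour genuinely overlaps a
  furniture class outside that class's region will be mislabelled.
- The calibration estimator assumes labelled samples are representative;
  it has no outlier model beyond quantile trimming.
- The synthetic renderer is deliberately non-photorealistic (flat
  colours, uniform noise, no shadows or reflections).
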