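# Methods

This note documents the models, numerical conventions and design
decisions behind `rootmorph`, and what the synthetic-image validation
does and does not demonstrate about real photographs.

## Scene model and calibration

The input is an 8-bit RGB photograph of an excavated root laid flat on a
uniform white background plate whose physical size is known (297 × 420 mm
and 610 × 420 mm boards are presets).  The plate serves two purposes:
contrast (roots are dark, the board is white) and metric calibration.
After cropping to the plate, the pixel pitch is
`p = mean(plate_width_mm / plate_width_px, plate_height_mm / plate_height_px)`;
pixels are assumed square, and a warning is raised when the two axis
ratios disagree by more than 2% (non-square pixels or uncorrected
perspective).  All physical outputs scale as `p` (length, diameter),
`p²` (areas) or `p³`-equivalent (volume via D²·L).

A camera sizing rule is included: the minimum pixel resolution along the
object is `ceil(2 × max_object_length / min_feature_size)` — two pixels
per smallest feature to be resolved (rounded up; a pixel count cannot be
fractional).

## Segmentation

1. **Grayscale.**  Default is the blue channel taken unchanged: for
   brown/dark roots on a white board the red and green channels separate
   the classes poorly while blue gives the largest gap.  The standard
   luma combination `0.299 R + 0.587 G + 0.114 B` (rounded half-up) is
   available as `weighted`.
2. **Threshold.**  If the 256-bin histogram, smoothed with a width-5
   moving average, has exactly two modes (local maxima above 1%
   prominence) separated by a *unique* interior minimum, and the split
   leaves at least 5% of the pixel mass on each side, the valley gray
   level is the threshold.  Anything else — unimodal histograms, broad
   or flat valleys, tied minima — falls back to the iterative
   (ISODATA-style) threshold: starting from the midpoint of the occupied
   gray range, `T ← round(½(mean gray ≤ T + mean gray > T))` until `T`
   is a fixed point.  Class means are real-valued; `T` is rounded
   half-up to an integer gray level so the fixed-point termination test
   is well defined, and `T` is clamped to keep both classes non-empty.
   The iteration is capped at 256 steps as a safety net (the map is
   monotone and bounded on integer gray levels; in practice it converges
   in a handful of steps).
3. **Polarity.**  Foreground is `gray ≤ T` by default (`dark_foreground`;
   roots are darker than the plate); the literal `gray > T` rule is
   available as `bright_foreground`.
4. **No-root guard.**  If the two classes induced by the final threshold
   have mean gray levels closer than `min_contrast` (default 10 gray
   levels), the image is declared rootless and an empty mask is
   returned: a blank plate has a single gray population, and any
   threshold inside it would label an arbitrary chunk of the plate as
   root.
5. **Median filter.**  Odd-sided windowed median (default 3 × 3) removes
   salt-and-pepper impulses.  Border pixels use the truncated window
   (only in-image cells; no invented padding values), taking the lower
   median when the truncated count is even, so the output is integral
   and deterministic.
6. **Morphology.**  Closing (fill cavities) then opening (remove debris
   specks), with a 3 × 3 all-ones structuring element by default.
   Dilation and erosion are implemented as explicit Minkowski
   shift-unions/intersections with a `border_value` parameter for the
   out-of-image region (background by default).  The erosion inside
   closing treats out-of-image pixels as foreground so closing is
   extensive up to the image edge.  The erosion/dilation duality
   `~erode(A, B, bv) == dilate(~A, B̂, 1−bv)` holds bit-exactly for every
   mask and is enforced by a property test.

Coordinates are row-major, 0-based, origin top-left; crop rectangles are
half-open.  The full pipeline is deterministic for fixed input and
configuration.

## Morphometry

**Projected area** is the foreground count times the pixel area.
**Lateral area** uses the cylinder-projection identity `S_l = π S_v`; a
literal stacked-cylinder mode multiplying by an explicit segment count is
retained for comparison but is not the default, because it grows with an
arbitrary discretization.

**Diameter.**  Maximal inscribed circles are sampled at every skeleton
pixel: the radius is the Euclidean distance transform minus 0.25 px.
The EDT measures pixel-center to pixel-center, so the true boundary lies
about half a pixel beyond the nearest background center (−0.5 px), while
a skeleton pixel sits on average a quarter pixel off the continuous
medial axis (+0.25 px); the net expected correction is −0.25 px.  The
residual error is a parity effect of up to ±0.25 px depending on whether
the local width is an odd or even number of pixels — about 1% for a root
20 px wide.  Radii are restricted to a configurable (0, 100] px window.
A circular-Hough alternative (`method="hough"`, peaks above 60% of the
strongest accumulator response) returns one circle per circular object
and is the right choice for disk-like calibration targets; the reported
`circle_count` is the number of samples for the inscribed method and the
number of detected objects for Hough.

**Length.**  The mask is thinned to a one-pixel 8-connected skeleton
(Zhang-style thinning via scikit-image).  The chain-code length counts
unique 8-adjacencies of the skeleton graph — each edge once, so junction
pixels are never double-counted — with axial steps weighted 1 and
diagonal steps √2.  A diagonal adjacency whose endpoints share an axial
skeleton neighbor is a shortcut across an existing corner and is
skipped.  Because thinning retracts the skeleton from each root tip by
roughly the local half-width, `measure_root` extends the length by the
local inscribed radius at every skeleton endpoint (tip correction; it
can be disabled).  The raw chain-code primitive is exact by
construction: an axial run of k steps measures exactly `k·p` and a
diagonal run exactly `k√2·p`.

The two-weight chain code is exact for axial and 45° paths but
overestimates digital straight lines at intermediate angles by up to
≈ 8% (a classical property of the `N₁ + √2 N₂` estimator); no
angle-dependent correction is applied.

**Volume** defaults to the equivalent cylinder `V = π (D/2)² L`
(dimensionally consistent and exactly consistent with the reported D and
L fields); a literal `mean radius × L` mode is retained for comparison.
A mask with no detectable circles reports diameter and volume as
*missing* (None / raised signal), never zero, so an absent measurement
cannot masquerade as a zero-volume root.

## Synthetic images and ground truth

The generator rasterizes straight constant-width segments (and filled
disks for diameter targets) on a plate: a pixel is root iff its center
falls in the half-open band `[−w/2, w/2)` of signed perpendicular
distance around the centerline with axial projection in `[0, length)`
(flat end caps).  Half-open bounds keep pixel counts exact while
avoiding the systematic one-pixel thinning that strict inequalities on
both sides produce whenever a band edge lands exactly on pixel centers.
Ground truth is computed from the geometry, never from the raster:
length is the sum of centerline lengths, single-band area is exactly
`length × width`, and union areas of branched roots are integrated on a
4× sub-pixel grid so junction overlap is never double-counted.
Salt-and-pepper noise (seeded, half salt half pepper, exact pixel count
`round(q·H·W)`) and an optional linear illumination ramp are applied
after rasterization.

The canonical fixture suite uses a 150 × 100 mm plate at 0.05 mm/px
(2 mm-wide, 100–120 mm-long tubes; a Y-branch; 2 mm and 6 mm disks; a
blank plate; noisy variants).  The pitch is chosen so a 2 mm root spans
~40 px and the quarter-pixel radius quantization stays near 1% of the
diameter; the plate is smaller than the physical presets simply to keep
the suite's rendering and measurement fast (the geometry, colors and
noise levels are the quantities under test, not the plate size).

What the synthetic validation does **not** cover: soil debris and
shadows, specular highlights, perspective and lens distortion, roots
with tapering width, overlapping/crossing roots, and texture within the
root.  Passing the fixture suite demonstrates the correctness of the
estimators under the scene model (uniform dark root on uniform light
plate), not robustness to every field condition.

## Validation statistics

Per parameter, against paired readings from a reference instrument:
sample standard deviations (n−1 denominator); totals-based absolute
error `Δ = Σx − Σy` and signed relative error `δ = Δ/Σy × 100%`; an
independent-samples t-test preceded by a classic Levene screen
(mean-centered absolute deviations, α = 0.05) that selects the
pooled-variance or Welch variant — both variants are always reported, as
instrument-comparison tables conventionally print both rows; and the OLS
line of reference on test readings (gain, offset, R²), whose
`gain·x + offset` maps test values onto the reference scale.  Two
constant identical samples yield t = 0, p = 1 by convention.  p-values
are two-tailed; the comparison verdict is "no significant difference"
when p exceeds the chosen α (default 0.01).

## Degenerate inputs and tie-breaks

- All-zero histograms raise an empty-input error; single-level
  histograms return that level with zero iterations.
- Thresholds are integers in [0, 255]; `bright_foreground` uses strict
  `>`.
- Even-count medians (truncated border windows only) take the lower
  median.
- An empty mask measures as all zeros with a `no_root` flag; missing
  diameter propagates to missing volume.
- The valley detector's "unique minimum" is strict: a tied two-bin
  valley (e.g. perfectly symmetric modes) falls back to the iterative
  threshold rather than guessing a tie-break.

## Problem sizes

The test suite renders the fixture plate once per session (eight
1.5-megapixel images) and runs the full pipeline on each; oracle
equivalence uses 100+ randomized 32 × 32 cases per primitive; the
t-test calibration uses 1000 null simulations at n = 30 per arm.  These
sizes were chosen to exercise every code path at realistic root
geometry while keeping the whole suite around a minute on one CPU.
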