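# rootmorph

Machine-vision measurement of excavated root systems from flatbed
photographs.  Roots (for example 2-year-old apple seedling root systems)
are laid on a white background plate of known physical size and
photographed; `rootmorph` segments the root from the plate and measures
the four standard morphological parameters — projected/lateral surface
area, average diameter, total length and volume — without a dedicated
root scanner.  It also ships the cross-instrument statistics used to
certify such a system against a reference instrument, and a synthetic
image generator with analytically known morphology for end-to-end
validation.

## Who it is for

Plant scientists and phenotyping engineers who need root morphology from
ordinary camera images, and anyone validating a low-cost imaging setup
against a commercial root scanner.

## The model

The root is treated as a stack of short circular cylinders (the
cylindrical approximation: roots grow uniformly along their axis, so
cross-sections are circles).  With pixel pitch *p* (mm/px) calibrated
from the plate size:

- **Projected area** `S_v = p² · N_a`, where `N_a` is the number of
  foreground pixels in the segmented silhouette.
- **Lateral surface area** `S_l = π · S_v` — for a cylinder seen
  side-on, the lateral area `π·d·l` is π times the projected area `d·l`.
- **Average diameter** `D = 2 · mean(rᵢ) · p`, with `rᵢ` the radii of
  maximal inscribed circles sampled along the skeleton (a circular-Hough
  alternative is available for disk-like targets), radii restricted to a
  configurable 0–100 px range.
- **Length** `L = p · (N₁ + √2 · N₂)`: the chain-code length of the
  one-pixel-wide skeleton, counting axial steps (`N₁`, length 1 px) and
  diagonal steps (`N₂`, length √2 px), plus a tip correction of one local
  radius per skeleton endpoint.
- **Volume** `V = π (D/2)² L`.

Segmentation follows the classic flow: crop to the plate → blue-channel
grayscale (dark roots on a white plate separate best in blue) → histogram
threshold (valley between the two modes when the histogram is clearly
bimodal, otherwise an iterative class-mean / ISODATA fixed point) →
median filter → morphological closing then opening.

The validation module computes, per parameter: sample standard
deviations, totals-based absolute/relative error, an independent-samples
t-test with a Levene variance-homogeneity screen, and the least-squares
cross-calibration line (gain, offset, R²).

## Worked example

```python
from rootmorph import (PixelCalibration, RootSpec, Segment,
                       preprocess_pipeline, measure_root)
from rootmorph.synthetic import render

# a 30 mm x 2 mm root on a 40 x 30 mm plate, 0.1 mm/px
spec = RootSpec(segments=[Segment((5.0, 15.0), (35.0, 15.0), 2.0)],
                plate_mm=(40.0, 30.0), mm_per_pixel=0.1)
img, truth = render(spec)

mask, thr = preprocess_pipeline(img)
meas = measure_root(mask, PixelCalibration(0.1))
print(f"threshold {thr.threshold} ({thr.method})")
print(f"length   {meas.length_mm:8.2f} mm   (true {truth.total_length:.2f})")
print(f"area     {meas.projected_area_mm2:8.2f} mm²  (true {truth.projected_area:.2f})")
print(f"diameter {meas.avg_diameter_mm:8.3f} mm   (true {truth.mean_width:.3f})")
print(f"volume   {meas.volume_mm3:8.2f} mm³  (true {truth.volume:.2f})")
```

Output:

```
threshold 140 (iterative)
length      30.03 mm   (true 30.00)
area        59.96 mm²  (true 60.00)
diameter    1.950 mm   (true 2.000)
volume      89.69 mm³  (true 94.25)
```

The iterative threshold lands midway between the root (blue value 30)
and plate (250) populations; length and silhouette area are recovered
essentially exactly, and the diameter/volume carry the expected
sub-pixel quantization of the inscribed-radius estimator (here a quarter
pixel on a 10-pixel radius).

Command-line equivalents:

```sh
rootmorph synth --spec tube.json --out imgs/       # render + manifest
rootmorph measure --in imgs/ --out results/ --plate 297x420
rootmorph validate --test a.csv --ref b.csv --out report/
```

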