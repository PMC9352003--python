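# applegrade

Automated quality grading of round fruit (modelled on Red Fuji apples) from
two non-destructive measurements:

* **Machine vision** — a single top-view RGB image yields three appearance
  quantities: the defective pixel ratio *t*, the aspect ratio *λ* (max
  horizontal over max vertical extent of the fruit contour), and the maximum
  cross-sectional diameter *W*<sub>p</sub> in pixels.
* **NIR chemometrics** — diffuse-reflectance spectra (400–1000 nm) predict
  the soluble-solids content (°Brix) through scatter correction (MSC, SNV),
  SPXY sample partitioning, and PLS regression on wavelengths selected by
  CARS (competitive adaptive reweighted sampling) or SPA (successive
  projections algorithm).

The two streams are combined by a four-grade decision rule: any surface
defect ⇒ *substandard*; sound but oval ⇒ *second class*; sound and nearly
round ⇒ *excellent* / *first class* / *second class* for high / medium / low
Brix. Size (XL/L/M/S) is graded independently from *W*<sub>p</sub> via a
pixel↔mm calibration line.

The package is aimed at people building or studying fruit-grading rigs:
every stage is a plain library function, a thin `applegrade` CLI wraps the
common workflows, and synthetic generators (`applegrade.synthfruit`) render
fruit images and simulate Brix-labelled spectra with known ground truth so
the whole pipeline is testable without hardware.

## The classifiers

With 0-based pixel coordinates (x = column, y = row), raw image moments
m<sub>pq</sub> = Σ x^p y^q f(x,y) give the contour centroid
(m₁₀/m₀₀, m₀₁/m₀₀); the radius sequence r_k from the centroid to the
contour's convex-hull vertices gives W_p = 2·max r_k.

| quantity | rule | grades |
|---|---|---|
| defect ratio *t* | *t* < 0.0018 vs ≥ 0.0018 | normal / defective |
| aspect ratio *λ* | λ ∈ [0.98, 1.05) vs outside | nearly round / nearly oval |
| diameter *W*<sub>p</sub> | ≥164 / ≥139 / ≥127 / <127 px | XL / L / M / S |
| Brix | ≥13 / ≥10 / <10 °Brix | high / medium / low |

The defect cutoff is the area ratio of a 3 mm blemish on a 70 mm fruit,
(3/70)² ≈ 0.18%. The pixel size cutoffs come from inverting the caliper
calibration W<sub>r</sub> = 0.4052·W<sub>p</sub> + 13.5015 (mm) at the
80 / 70 / 65 mm class boundaries.

## Worked example

Render a synthetic apple and grade its appearance:

```bash
$ applegrade simulate images --n 1 --seed 7 --out demo/   # or render_apple() in Python
$ applegrade grade-image apple.png
{
  "defect_ratio": 0.006238662006105925,
  "aspect_ratio": 1.017751479289941,
  "diameter_px": 171.5747117081863,
  "defect_label": "defective",
  "shape_label": "nearly_round",
  "size_label": "extra_large"
}
```

This fruit was drawn 170 px wide with aspect 1.02 and a planted defect
ratio of 0.0060; the pipeline measures t = 0.0062 (within 5%),
λ = 1.018 and W_p = 171.6 px, and labels it defective (t ≥ 0.0018),
nearly round (0.98 ≤ λ < 1.05) and extra large (W_p ≥ 164). A defective
fruit is graded *substandard* regardless of its Brix:

```python
>>> from applegrade import grade_apple, measure_appearance
>>> import imageio.v3 as iio
>>> res = measure_appearance(iio.imread("apple.png"))
>>> grade_apple(res, "high").quality_grade
'substandard'
```

Fit the pixel→mm size calibration from (W_p, W_r) pairs:

```bash
$ applegrade fit-calibration pairs.csv --out cal.json
Wr = 0.4052 * Wp + 13.5015  (R^2 = 1.0000)
```

Train and compare Brix models on simulated spectra:

```bash
$ applegrade simulate spectra --n 168 --seed 0 --spectra-out sp.csv --brix-out bx.csv
$ applegrade fit-brix sp.csv bx.csv --method cars-pls --seed 0 --out model.json
$ applegrade benchmark-brix --seeds 20
```

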