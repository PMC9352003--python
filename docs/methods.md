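# Methods

This note documents the models and estimators implemented in `applegrade`,
the synthetic data they are validated against, and the numerical choices
made where the design was genuinely open.

## 1. Vision pipeline

**Model.** A fruit photographed from above on a light background is treated
as a single dominant connected region whose colour saturates against a
low-saturation, high-value background. The processing chain is:

1. gamma correction `v → 255 (v/255)^γ` per channel (default γ = 1.2,
   mild contrast stretch);
2. Gaussian smoothing (σ = 1.5 px, reflective boundaries);
3. HSV segmentation: background := pixels with saturation ≤ 0.25 **and**
   value ≥ 0.55; fruit := complement. Dark blemishes have low value and
   therefore stay inside the fruit region; specular highlights classify as
   background but become interior holes;
4. morphological opening then closing with a disc footprint (radius 3 px),
   then hole filling — removes stray speckle and re-absorbs highlights and
   the fruit tip;
5. largest 8-connected component → Moore boundary trace (ordered pixel
   boundary, ties between equal-area components broken by row-major first
   occurrence).

**Measurements.** Raw moments m_pq = Σ x^p y^q f(x,y) give the region
centroid. The defect ratio t is the count of fruit pixels whose BT.601
luminance (0.299 R + 0.587 G + 0.114 B) falls below a grey threshold
(default 60 on the 8-bit scale, chosen so blemishes at ≤ 40% of the fruit's
luminance are captured after gamma correction) divided by the fruit pixel
count. The aspect ratio λ uses inclusive pixel extents
(max − min + 1) of the boundary points. The maximum cross diameter
W_p = 2·max_k r_k is evaluated over convex-hull vertices only; the maximum
centroid-to-boundary distance is attained on the hull, and the equivalence
with brute force over all boundary points is asserted in the tests.

**Classifiers.** t < 0.0018 → normal, else defective (the cutoff is the
area ratio (3 mm / 70 mm)²). λ ∈ [0.98, 1.05) → nearly round, else nearly
oval; the half-open interval follows the verbal definition of the oval
class ("≥ 1.05 or < 0.98") — the printed classifier is internally
inconsistent at λ = 0.98 and the prose reading was adopted. Size uses
pixel thresholds 164/139/127 obtained by inverting the calibration line
W_r = 0.4052 W_p + 13.5015 at 80/70/65 mm and rounding to the nearest
integer (164.11 → 164, 139.43 → 139, 127.09 → 127). W_r is in
millimetres throughout; the national size classes are usually quoted in
cm, but the calibration line only reproduces the published pixel
thresholds with mm units.

**Calibration fit.** Ordinary least squares of W_r on W_p
(`scipy.stats.linregress`), reporting slope, intercept, R², and the
residual variance SSE/(n−2).

## 2. Chemometrics

**Preprocessing.** Reflectance correction R = (I − I_d)/(I_w − I_d);
wavelength decimation keeping indices 0, s, 2s, … (a 1771-point 400–1000 nm
grid at s = 3 leaves 591 points); MSC (per-spectrum least-squares affine
fit against the mean spectrum, corrected = (R − a)/b); SNV (per-spectrum
standardization, population SD). Default composition is MSC then SNV;
each stage is individually switchable. MSC with a data-driven (mean)
reference is only approximately idempotent; with a fixed reference it is
exactly idempotent because the least-squares residual is orthogonal to the
reference.

**SPXY partitioning.** Kennard–Stone farthest-point accretion on
d_xy(p,q) = d_x(p,q)/max d_x + d_y(p,q)/max d_y, with Euclidean d_x on the
preprocessed spectra and |Δy| on Brix. The first two calibration picks are
the globally most distant pair; calibration size is round(N·c/(c+p))
(168 at 3:1 → 126/42).

**PLS1.** NIPALS deflation with mean-centering only (MSC/SNV already
normalize scale): w = X′y/‖X′y‖, t = Xw, p = X′t/t′t, q = y′t/t′t, deflate
both blocks; collapsed coefficients B = W(P′W)⁻¹q so prediction is affine
in the input spectrum. With a single response no inner iteration is
needed and the factorization is exact; at full rank it reproduces ordinary
least squares (tested). Component count is chosen by the minimum of
k-fold RMSECV (default 10 folds, shuffled once from the seed; no one-SE
rule; capped at 20, or 15 in the benchmark harness).

**CARS.** Per run i of n (default 50): (1) fit PLS on a Monte-Carlo
subsample of 80% of the calibration rows over the current subset and take
|B| as fitness weights; (2) forced retention keeps the top
K_i = round(r_i·W) variables, where r_i = a·e^(−k·i) is calibrated so
K_1 = W and K_n = 2; (3) adaptive reweighted sampling draws the *next*
run's subset from the survivors **without replacement** with probability
∝ |B|, sized by the next EDF count. RMSECV (fixed folds, ≤ 10 components)
is recorded for every run's subset and the minimal-RMSECV subset is
returned. A with-replacement ARS variant (unique survivors of K_i draws)
was tried first; its subset size collapses geometrically (≈ 0.65× per
run), exploring only ~15 sizes and making the selection unstable, so the
without-replacement draw sized by the EDF schedule — which matches the
smooth decay seen in published CARS traces — was adopted.

**SPA.** Forward chains: from a start column, repeatedly add the column
with the largest norm after orthogonal projection onto the complement of
the span of the selected ones (sequential deflation; duplicated columns
project to zero and are never co-selected). Chains are grown from every
candidate start column to k_max; scoring every (start, k) pair by
cross-validated regression would cost O(W·Δk·folds) model fits, so the
best chain is picked by calibration RMSE of an OLS fit at k_max and only
that chain's prefixes are scored by cross-validated OLS RMSE over
k ∈ [k_min, k_max] (defaults 30–50).

**Evaluation.** Pearson correlation and RMSE on calibration (R_c, RMSEC)
and prediction (R_p, RMSEP) sets. Zero-variance truth or predictions make
the correlation undefined; it is reported as NaN while the RMSE is still
returned.

**Brix grades.** ≥ 13 °Brix → high, [10, 13) → medium, < 10 → low.

## 3. Synthetic generators

All generators are pure functions of their spec including the seed.

**Images.** An axis-aligned ellipse (axes d × d/aspect) with mild radial
shading (8%) in a flat red hue on a light background (level 245), optional
dark blobs (35% of fruit colour) totalling a target fraction of the fruit
area, an optional specular highlight, and Gaussian sensor noise (SD 2
counts). Ground truth t, λ, W_p are computed from the drawn raster
(extents and pixel counts), not from the measurement pipeline. The fixture
sampler draws diameters 105–190 px, aspects in three branches (round
0.995–1.035; oval 0.90–0.965 and 1.065–1.13), and defect fractions either
≈ 0 or 0.004–0.015, keeping a margin to every classifier cut point (≈ 4 px
of diameter, ≈ 0.015 of aspect, a factor ≈ 2 of defect ratio). This
emulates a study population of unambiguous class members; agreement rates
measured on it say nothing about borderline fruit, where rasterization
noise alone would flip labels.

**Spectra.** On a 1771-point 400–1000 nm grid, each sample is

    R_i(λ) = b_i · [ baseline(λ) − Brix_i · Σ_b g_b G(λ; c_b, w_b)
                     + Σ_j a_ij S_j(λ) ] + a_i + ε_i(λ),

with Brix_i from a truncated normal (mean 11.7, SD 1.1, range 8.9–14.6
°Brix — note the truncation shrinks the realized SD by ≈ 3.7% relative to
the parent; tests compare against the truncated-normal moments), five
Gaussian absorption bands at 680/760/840/912/962 nm (σ 8–12 nm, depths
0.020–0.032 reflectance units per °Brix) standing in for sugar C–H/O–H
overtones, fixed-shape interferent species S_j (8 Gaussians, σ 10–30 nm,
centers ≥ 25 nm away from the sugar bands, per-sample amplitudes
N(0, 0.015)) standing in for other absorbers, multiplicative/additive
scatter b_i ~ N(1, 0.08), a_i ~ N(0, 0.02), white noise ε with SD 0.003,
and additional detector noise of SD 0.06 outside 660–985 nm, emulating the
low lamp energy and detector quantum efficiency at the spectral edges that
the black/white correction amplifies.

The noise geometry is what differentiates the three Brix models, and the
defaults were calibrated once so that the qualitative outcome of a real
grading study is reproduced: wavelength selection matters. Two simpler
universes fail to do so — with white noise only, full-spectrum PLS
averages the noise away and is near-perfect; with strong broad
interferents, the MSC/SNV scale estimates are corrupted and the narrow
band signal is destroyed for every model. With edge-concentrated noise
plus band-avoiding interferents, CARS-PLS concentrates on the band
region (typical subsets of 20–90 wavelengths) and attains prediction
R_p ≈ 0.93–0.96, SPA spends part of its 30–50 picks on high-variance edge
columns and lands in between, and full-spectrum PLS is dragged down to
R_p ≈ 0.5–0.7 by the ~290 noisy edge channels. What a passing benchmark
shows is that the implemented selection machinery finds a planted signal
under this noise geometry; it does not certify performance on real
spectrometer data, whose confounders (nonlinearity, temperature drift,
pigment variation) are richer.

**Calibration pairs.** W_p uniform on 110–200 px,
W_r = 0.4052·W_p + 13.5015 + N(0, noise_sd²) mm.

## 4. Problem sizes and determinism

The test suite and the acceptance script use 200 rendered fixtures for the
appearance classifiers and 20 simulated spectral campaigns (N = 168,
W = 1771 → 591) for the model comparison, with all randomness derived from
explicit seeds; a full acceptance run completes in a few minutes on one
CPU. CARS uses 50 runs and 10-fold cross-validation; the benchmark caps
PLS at 15 components.

## 5. Known limitations

* Segmentation assumes a light, low-saturation background; it will fail on
  cluttered or dark scenes.
* The defect detector is a single global grey threshold — graded shading,
  russeting, or stem cavities are out of scope.
* λ uses axis-aligned extents; a tilted oval fruit can measure as round.
* The spectral generator is linear in Brix by construction, so it cannot
  probe the nonlinear response of real tissue.
* `evaluate_model` reports NaN correlations for degenerate sets rather
  than raising, so downstream code must tolerate NaN.
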