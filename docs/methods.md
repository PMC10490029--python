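# Methods

## Measurement model

The device's raw measurement is the mean HSV Value, V̄, of a cuvette
photograph over a region of interest (ROI). The HSV conversion is the
classic sector rule on channels normalized to [0, 1]: V = max(R′, G′, B′),
S = (max − min)/max (0 when max = 0), and H from the three-case rule with a
+360° wrap, H ∈ [0, 360). Achromatic pixels (max = min) have no defined
hue; the type carries H = 0 plus an `achromatic` flag so the conversion is
total — the quantification path only consumes V, so the convention is
inert. V̄ is reported on a 0–100 percent scale by default because the
calibration coefficients are dimensionally coherent on that scale: with
NO₃⁻ ∈ [0, 10] mg L⁻¹ the law NO₃⁻ = 24.82 − 0.26·V̄ implies
V̄ ∈ [57.0, 95.46], which only makes sense in percent. A unit (0–1) scale
is available.

The photo-processing chain, in order:

1. **EXIF orientation correction** — all eight orientation codes,
   including the mirrored ones (2, 4, 5, 7), are mapped to upright pixels;
   unknown codes degrade to a no-op with a warning. Pillow's
   `exif_transpose` is used as an independent oracle in tests; the
   transforms themselves are numpy rot90/flip compositions.
2. **Downscale** so the longest edge is 1080 px (bilinear). Upscaling is
   never performed: the step is a normalization of camera resolution, and
   interpolation cannot add signal.
3. **ROI crop** — a manual half-open rectangle or, by default, the
   centered f×f fraction of the image with f = 0.5. The true cuvette ROI
   geometry of the original app is unpublished; the centered-fraction
   default captures the liquid column of a centered cuvette and a manual
   override is always available.
4. **V-channel histogram equalization** over the ROI. V is quantized to
   256 levels and remapped through the ROI's own cumulative distribution,
   v → CDF(v), a monotone non-decreasing map; the remap rescales the RGB
   triplet, which leaves H and S exactly unchanged (both are functions of
   channel ratios). An ROI whose V occupies a single level carries no
   contrast to redistribute and passes through unchanged — without this
   convention the plain CDF would send every constant patch to V = 1 and
   destroy the concentration signal of flat fixtures. Whether the original
   app equalizes full RGB or one channel is unstated; V-only equalization
   avoids hue distortion and matches the V-based quantification.
5. **Mean V**, then the affine calibration.

## Calibration and device metrics

`LinearCalibration` regresses concentration on V̄ (classical direction,
matching the printed form of the law), by closed-form OLS. Negative
predictions are clamped to zero with a `below_range` flag and the raw
value preserved — a field instrument should report "below range", not
error. Predictions above the fitted concentration range are flagged
`extrapolated`.

- Sensitivity σ = |slope|, in mg L⁻¹ per V-percent.
- LOD = 3.3·SD/σ, the usual normal-noise convention.
- %RSD = SD/mean × 100 with the n−1 sample SD throughout (the convention
  is not fixed by the source material; n−1 is the unbiased-variance
  default).
- %bias = (known − mean measured)/known × 100; positive values are
  underestimation.
- Device characterization pools SD across QC sets as the root mean square
  of per-set SDs (unbiased for the pooled variance under homoscedasticity
  and equal replicate counts), averages %RSD and %bias across sets, and —
  when day labels are supplied — reports inter-day precision as the RSD of
  per-day mean concentrations. The inter-day formula is an assumption; the
  original report prints a value without defining the computation.

## Replicate agreement

Pearson r uses the t transform, t = r√((n−2)/(1−r²)) on n−2 df, two-sided.
Kendall's tau-b (tie-corrected) delegates to scipy, which uses the exact
null for small untied samples. The RCR (roughness of concomitant ranks)
test is implemented from its construction: sort the observations by x,
rank the accompanying y values, and take Σ(rᵢ₊₁ − rᵢ)² as the statistic.
Smooth x–y relationships — monotone or not — give small roughness (minimum
n−1 for strictly monotone ones), so the test detects nonlinear,
non-monotone association that tau misses; the p-value is the left tail of
a seeded permutation null (default 9999 permutations, add-one estimator).
The cited construction could not be confirmed against its original
description, so deviations from that reference are possible; the
implementation is documented here as the contract. Ties in x are broken by
stable input order with a warning. No multiple-testing correction is
applied to the pairwise matrices by default, matching the original
reporting; a Holm-corrected variant can be obtained by post-processing the
tidy output.

The device-vs-laboratory comparison uses Welch's unequal-variance t-test
by default — "independent samples t-test" does not promise equal
variances, and Welch is the safer default — with the pooled Student form
behind a flag.

## Geostatistics

The empirical semivariogram is the method-of-moments estimator
γ(h) = Σ(zᵢ−zⱼ)²/2N(h) on equal-width lag bins; defaults n_lags = 12 and
max_lag = half the maximum pairwise distance (standard practice). Model
fitting minimizes Σ N(h)(γ̂ − γ_model)² over (nugget, partial sill, range)
with non-negativity bounds, multi-started over a coarse grid of candidate
ranges and sill splits to avoid local minima; the result is deterministic
given the input. All five families (Gaussian, spherical, exponential,
circular, linear) use the *effective range* convention — γ reaches ≈95% of
the sill at h = range (exactly the sill for the compactly supported
families) — matching how GIS software reports the parameter, since the
published parameters come from such software.

Ordinary kriging solves the global system (all samples; the surveys this
targets are a few hundred points, so a dense solve with a cached LU
factorization is trivial) with the unbiasedness row forcing Σwᵢ = 1.
γ(0) = 0 on the matrix diagonal; the right-hand side uses the h → 0⁺ limit
(nugget included at zero distance), so with nugget = 0 kriging is an exact
interpolator with zero variance at data points, while with nugget > 0 it
smooths there — the prediction need not honor the observation, and the
kriging variance stays positive. Duplicate sample locations are averaged
with a warning before the solve. Leave-one-out cross-validation reports
the RMSE of residuals and the OLS regression of observed on predicted —
the form map-accuracy tables print. Whether such published regression
lines come from LOO or from a device-vs-laboratory regression is
ambiguous; LOO is implemented, and a direct regression can be composed
from the replicate-statistics module. Class-area tabulation uses
half-open [low, high) intervals with an overflow class and a warning for
out-of-envelope cells.

Coordinates are assumed planar (projected meters). The mg L⁻¹ (extract) →
kg ha⁻¹ (field) conversion is survey-specific (extraction ratio, bulk
density, sampling depth) and enters as a user-supplied factor; none is
hard-coded.

## Synthetic data

The generators exist so every stage can be tested against a known truth;
all are pure functions of their spec including the seed.

- **Cuvette images** are flat patches: hue fixed at the yellow of the
  nitrate complex (55°), saturation rising with concentration, V set by
  inverting the calibration law, with optional per-pixel Gaussian V noise.
  They are deliberately not photorealistic — the pipeline consumes only
  mean V, so flat patches give exactly the test power needed. What passing
  tests therefore do **not** show: robustness to vignetting, specular
  highlights, cuvette edges in the ROI, or illumination drift in real
  photographs.
- **Calibration/QC tables** invert the law and add Gaussian V noise
  (default simulation noise SD 0.3 V-percent, a mid-range value consistent
  with the percent-level RSD the device class achieves).
- **Gaussian random fields** draw jointly Gaussian values with covariance
  C(h) = partial_sill·(1 − g(h/range)) via Cholesky (with a tiny jitter
  retry), plus independent N(0, nugget) noise, at uniform random locations
  — so the realized semivariogram matches the target model in expectation.
  Recovery experiments use nugget 16, partial sill 4 (ratio 0.8, the
  regime the field survey reported), range 30 on a 100×100 domain with 150
  points.

## Numerical choices and limitations

- 8-bit quantization bounds the image pipeline's accuracy: one V level is
  100/255 ≈ 0.39 percent, i.e. ≈0.05 mg L⁻¹ through the 0.26 slope; the
  end-to-end recovery tolerance of 0.2 mg L⁻¹ sits well above it.
- Variogram fitting on white-noise fields can attribute chance structure
  in the sparsely populated first lag bin to a short-range component in a
  minority of realizations; the structured fraction is small in the
  median. Single-realization variogram parameters are, as always,
  noisy — ratio-recovery claims are stated in the median over seeds.
- Published absolute variogram parameters and map-area percentages depend
  on the original survey's raw coordinates and ArcGIS's internal binning
  and fitting choices, which are unpublished; they are reproducible only
  at the level of the nugget/sill ratio arithmetic and of
  parameter-recovery properties on synthetic fields.
- Only isotropic variograms and ordinary (not universal or co-) kriging
  are supported; no moving-neighborhood search. Affine calibration only —
  no exponential or polynomial families.
- Test problem sizes (e.g. 150-point fields, 20 recovery seeds, 200
  calibration simulations, 96-px fixtures) are chosen as the smallest
  sizes at which the estimators' sampling noise is comfortably inside the
  asserted tolerances.
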