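# Methods

This note documents the models, estimators, numerical choices and known
limitations of `ctiq`, in the order the pipeline runs them.

## Phantom model

The synthetic slice is a two-tissue edge: plateaus at `hu_high` (default
+50 HU, muscle-like) and `hu_low` (−100 HU, fat-like) joined by a *linear*
ramp of exact gradient `edge_slope_hu_per_mm` (< 0 when traversing bright →
dark). A linear ramp, rather than a sigmoid edge-spread function, was chosen
so that "steepest slope" has a closed-form ground truth and slope recovery is
an exact test. The transition width follows as
w = (hu_low − hu_high)/slope. On top of the template the generator can add a
second-order polynomial drift a + bx + cy + dx² + exy + fy² (coordinates in
mm, centered on the image) emulating low-frequency shading, and i.i.d.
Gaussian noise.

Rasterization evaluates the template at pixel *centers* (no area averaging);
coordinates are x = col·spacing, y = row·spacing from the top-left pixel
center, angles counter-clockwise from +x. The border line passes through the
image center; its normal is the border direction rotated −90°, and the bright
plateau lies on the negative-normal side, so transition slopes are negative.

What the phantom does **not** emulate: correlated (non-white) noise such as
that produced by iterative or deep-learning reconstruction, beam-hardening
and streak artifacts, curved interfaces, partial-volume averaging, or
anatomy. Passing tests therefore demonstrate estimator correctness under
white noise on straight edges, not clinical accuracy on patient images; on
real reconstructions the noise texture in particular can shift both the noise
estimate and the slope bias.

Rater tables are simulated as latent item quality plus Gaussian rater noise,
rounded half-up and clipped to the Likert scale (half-up so integer scores
are platform-reproducible). Dose cohorts draw CTDIvol and scan length from
truncated normals and define DLP = CTDIvol × scan length exactly.

## Profile extraction and sharpness

Ten stations are placed evenly (endpoints inclusive) along the marked border
segment; each profile is sampled by bilinear interpolation at uniform step
`step_mm` over ±4.5 mm. The default step is half the pixel spacing —
Nyquist-safe against the bilinear field; the half range is realized as the
nearest whole number of steps so position 0 always lies on the border.

Baselines are the means of the outer `plateau_fraction` (default 0.25) of
samples on each side: far enough from the border to exclude the transition
for any clinically plausible transition width, while still averaging ≥ 20
samples at default settings. Fewer than 3 samples per plateau is an error;
flat or inverted profiles are flagged rather than assigned baselines.

"Steepest slope over three points" is implemented as the least-squares slope
over every window of three *consecutive resampled samples* (for uniform
spacing this reduces to the central difference (g[i+2] − g[i])/(2h)), taking
the most negative window; ties are broken toward the window center nearest
the marked border, then first occurrence, for determinism. The reported
`distance_mm` is the signed span of the winning window (−2h for a falling
edge). Non-uniform sampling is rejected because the window statistics assume
a common h. Per-image values are component-wise medians over the ten
profiles (numpy convention: even counts average the central pair).

Two quantified estimator properties (both asserted in the tests):

* **Resolution limit.** With step h = spacing/2 the estimator cannot report
  magnitudes beyond contrast/(2·spacing); a noiseless under-resolved ramp
  saturates exactly at that value, while resolved ramps (w ≳ 2 pixels)
  recover the true slope to machine precision.
* **Noise bias.** Taking the minimum over many noisy 3-point windows biases
  the estimate steep. At noise SD 5 HU and the two reference conditions
  (−168.4 HU/mm at 0.234 mm; −94.5 HU/mm at 0.469 mm) the median bias is
  ≈ +13% and +8% respectively — inside the 15% band the pipeline is
  validated against, and direction-preserving: the steeper phantom is
  ordered steeper in every paired run.

## Noise estimation

Edge detection is a central-difference gradient-magnitude threshold in
HU/mm (default 50; exposed in configuration). This is the simplest detector
satisfying the procedure; any detector producing a conservative transition
mask can be substituted.

The sliding window is round(5 mm / spacing) pixels, forced odd and ≥ 3, at
stride 1 ("sliding" read as dense evaluation). In each window containing no
edge pixel, the full 6-coefficient second-order polynomial is fitted by least
squares and subtracted; the residual SD uses the n−1 denominator by default
(the plain SD of the residuals), with an n−6 degrees-of-freedom correction
available via `fit_dof_correction` — the default slightly *under*-states the
per-window SD (factor √((n−6)/(n−1)), ≈ 0.98 for 21 px windows).
Numerically, each window is mean-centered before projection onto a QR
orthonormal basis of the design, so residuals are exact to machine precision
even over large HU offsets; noiseless quadratic surfaces give residual SD
≤ 1e-14.

The noise value is the **minimum** of the map (ties: first in row-major
order). The minimum of thousands of correlated window SDs under-estimates
the true σ; on white noise over 200 × 200 px at the 0.234 mm pitch the
estimate lands at ≈ 0.86–0.89 σ, and the validated band is [0.7 σ, σ].
At coarser pitches (11 px windows) the window-SD distribution is wider and
the minimum can fall marginally below 0.7 σ. The map is returned alongside
the estimate so callers can report the spread; detrending is exactly
invariant under adding any global second-order polynomial.

The separate homogeneous-region pre-selection (lowest *raw* SD, edge-free)
only localizes the measurement region for reporting; the noise value always
comes from the detrended map minimum.

## SNR, CNR

SNR = upper baseline / noise (the brighter tissue, muscle, is "signal");
CNR = (upper − lower) / noise. Noise ≤ 0 (e.g. a noiseless or constant
image) raises an undefined-ratio error rather than returning NaN or inf.
Full precision is kept internally; serialization rounds to 1 decimal.

## Dose

normalized DLP = CTDIvol × 25 cm (reference neck scan length); effective
dose = DLP × k, k = 0.0058 mSv/(mGy·cm) for head-and-neck CT, with a small
table of other ICRP adult body-region factors in `ctiq.dose.K_FACTORS`.
Output rounding is half-up (2 decimals mSv, 1 decimal mGy·cm) and applied
only at serialization so printed figures follow from exact arithmetic.

## Agreement and comparison statistics

ICC is fixed to the two-way mixed, consistency, single-rater form ICC(3,1) —
the most common reading of "two-way mixed, consistency" — with the
average-measure ICC(3,k) behind a flag. Tables with zero between-item
variance return an explicitly flagged undefined result. The printed band
edges (moderate up to 0.75, good from 0.76) leave (0.75, 0.76) unassigned;
the boundary is resolved at 0.755.

Cohen's κ is restricted to two raters on integer (Likert) categories, since
κ is not meaningful on continuous data; p_e = 1 (both raters constant and
equal) is flagged undefined. Mann–Whitney uses exact enumeration of all
C(n+m, n) assignments when both n, m ≤ 8 (correct under ties, where the
classical exact distribution is not), otherwise the tie-corrected normal
approximation with continuity correction. The package also exposes the
paired signed-rank alternative through scipy for paired designs; the
unpaired test is the default to match common practice on reader scores.
KS normality is tested against a normal with the sample's own mean/SD, so
its p-value is conservative (Lilliefors caveat); `describe` uses it at
α = 0.05 to choose between mean ± SD and median/IQR (linear-interpolation
quartiles), treating constant samples as non-normal.

## Problem sizes and determinism

Monte-Carlo validations use 24 mm phantoms for slope recovery (50–200
seeds), 200 × 200 px fields for noise (up to 100 seeds per σ), and 2000
simulations for the rank-test type-I check — sizes at which every Monte-Carlo
band in the tests is stable to reruns. All randomness flows from explicit
integer seeds (one `numpy` Generator per artifact); identical spec + seed
gives bit-identical images, tables and reports.

## Known limitations

* White-noise phantom only; no claim about spatially correlated noise.
* The linear-ramp edge makes slope recovery exact but is not an optical
  edge-spread function; absolute slopes on real scanners also reflect the
  reconstruction kernel.
* The min-of-map noise statistic is biased low by construction (documented
  above) — comparisons between images with equal window geometry remain fair.
* The steepest-window span (`distance_mm`) is reported as defined here
  (signed span of the winning 3-sample window); it depends on the resampling
  step, not only on the image.
* Single-slice, isotropic-spacing 2D analysis only.
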