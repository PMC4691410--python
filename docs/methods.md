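# Methods

## Measures and models

Three regional measures are analyzed per scan, for each of 33 bilateral
Desikan-Killiany cortical regions: cortical thickness (mm), cortical MWF
(fraction of signal attributed to myelin-trapped water, ~0.05–0.15 in this
age range), and adjacent white-matter MWF (~0.1–0.3). Development of each
measure with age t (days, corrected to a 40-week gestation) is modelled as
logarithmic, `y = a·ln(t) + b`, with natural logarithm of age in days.
That convention is fixed by the reference coefficient table itself: only
under ln(days) do the published (a, b) pairs evaluate to plausible
thickness (≈2.7–3.1 mm) and MWF (≈0.09–0.13) over 363–2198 days.

Model selection compares logarithmic, linear, and quadratic (in raw days,
not ln-days) OLS fits via `BIC = n·ln(RSS/n) + k·ln(n)` with k the number
of regression coefficients (2, 2, 3). No `+1` for the error variance is
included; since all candidates are fitted to the same data the constant
cancels in every ΔBIC. BIC magnitudes are therefore comparable between
model forms but are not expected to reproduce any externally reported
absolute BIC values. A perfect fit (RSS = 0) is flagged with a −∞
sentinel. Near-ties are reported at ΔBIC < 2 (the conventional "barely
worth mentioning" band); exact ties resolve deterministically in the order
logarithmic, quadratic, linear.

All 177 scans are pooled as independent observations, including repeat
scans of the same child. This mirrors the degrees of freedom evident in
the reference correlation table (p-values there are consistent with
n = 177 under the t transform). A per-child random intercept can be
switched on in the generator to study the consequences of that
simplification, and a subject-aware analysis can be built from the scan
table's `child_id` column, but the default analysis is pooled.

## Adjacent-white-matter sampling

A parcel's adjacent WM is sampled by (1) blurring the binary parcel mask
with a 2-D Gaussian kernel of 4 mm FWHM (σ = FWHM/(2√(2 ln 2)) ≈ 1.699 mm),
applied slice-wise; (2) zeroing every voxel whose tissue class is not
white matter; (3) taking the weighted mean of the quantitative map under
the surviving weights. Decisions that were genuinely open:

- **Blur plane.** The anatomical plane of the 2-D kernel is configurable
  (`BlurSpec.plane`), defaulting to the first two voxel axes — the axial
  plane on the phantoms. Results on phantoms are insensitive to the choice
  by symmetry; on real data the plane should match the acquisition plane.
- **No binarization.** The blurred weights are used directly as weights in
  the regional mean rather than being thresholded, since the blurred mask
  is superimposed as-is; `weighted_regional_mean` is invariant to global
  weight rescaling, so unit-sum truncation error is immaterial. A
  binarize-at-threshold variant is a one-liner on top of
  `adjacent_wm_mask` (`weights > tau`).
- **Kernel discretization.** The discrete kernel is truncated at 4σ and
  normalized to unit sum, so each slice's mass is conserved up to
  truncation (<1e−6). Tests verify equality with a brute-force O(N·K)
  convolution to 1e−10.
- **Subtraction = WM restriction.** "Remove cortex and non-brain" is
  implemented as "retain only tissue class WM", equivalent for a
  three-class label table (background / WM / cortical parcels). A region
  whose blurred mask reaches no WM voxel above a 1e−6 floor raises a
  "no adjacent WM" error (or is skipped with a warning in the batch
  extractor).
- **Registration.** Maps and labels are assumed voxel-aligned (identity on
  phantoms); no resampling is implemented.

## Statistics

Residuals are computed per (region, hemisphere, measure) by subtracting
the fitted logarithmic trajectory; OLS with an intercept makes them
mean-zero by construction. Pearson product-moment correlations between
residual pairs get two-sided p-values from `t = r√(n−2)/√(1−r²)` with
n − 2 df (|r| = 1 maps to the p = 0 sentinel). Family-wise correction uses
the Holm–Bonferroni step-down: sort ascending, reject while
`p_(k) < α/(m−k+1)`, stop at the first failure. The default family is the
33 regions of one hemisphere for one measure pair (m = 33, α = 0.05),
configurable to a pooled 66-region family; the per-hemisphere default
follows the stated "33 bilateral region comparisons" correction, though
the exact family in the reference analysis is not fully recoverable from
the published significance flags alone.

The ideal T₁-weighted signal is `S(T₁) = 1 − 2e^(−TI/T₁)` with
TI = 950 ms (the MP-RAGE inversion time of the acquisition protocols);
contrast is the signed difference `S(T₁_wm) − S(T₁_gm)`, positive whenever
WM T₁ is shorter than GM T₁. A Michelson-style normalized variant is
available (`mode="michelson"`). Contrast–thickness correlations
age-residualize both series by default, consistent with the other
couplings; raw-mode correlation is available since either reading of the
procedure is defensible.

## Synthetic cohort: what it emulates, and what it does not

`CohortSpec` defaults encode the study layout: 134 children, of whom 36
are scanned at least twice and 7 (a subset of the 36) three times — 177
scans; ages 363–2198 days; repeat gaps Gaussian around 365 days (SD 60,
floored at 1 day, truncated to the age range). First-scan ages are uniform
over the range by default; the cohort's reported mean (1044) and SD (523)
are not reproducible by any age distribution supported on [363, 2198]
together (the maximum SD of a truncated normal with mean 1044 on that
support is ≈499), so a truncated-normal option with loc = 1044,
scale = 523 is provided and its realized moments (mean ≈ 1125, SD ≈ 485)
are documented and tested against the analytic truncated moments.

Measures are generated as trajectory mean plus a trivariate Gaussian
residual whose correlation matrix is the published region-wise coupling
structure (all 33 published matrices are verified positive definite) and
whose SDs default to 0.1 mm (thickness) and 0.01 (both MWFs) — the scale
of scatter consistent with the reference trajectories. Regional T₁ is
flat by default (GM 1400 ms, WM 900 ms, order-of-magnitude values for 3 T
early childhood; no regional T₁ values were published) with optional
logarithmic age drift and noise. MWF values are clipped to [0, 1].

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: within-subject correlation of repeat scans
(off by default), spatial correlation between neighboring regions,
non-Gaussian or heteroscedastic residuals, segmentation or registration
error, and any dependence of measurement noise on age. Parameter-recovery
and type-I-error results on this generator validate the estimator
implementations, not the biological claims.

The phantom is a concentric cuboid: WM core, GM ribbon of configurable
thickness, background margin; shell and core are cut by equal angular
sectors so every parcel owns a stretch of adjacent WM with its own
quantitative values. It is deliberately minimal — enough geometry to
exercise blurring, subtraction, and averaging, not an anatomical head
model. The default grid is 24×24×12 voxels at 1.2 mm isotropic (the
acquisition resolution), with a diagonal affine.

## Problem sizes and numerical choices

The validation studies run at the study scale (n = 177 scans): 100 cohorts
for parameter recovery, 200 replicates for BIC selection and for the
zero-coupling family-wise type-I study (single hemisphere, 33 regions).
The long-run BIC logarithmic-selection rate under those conditions is
≈0.93. Geometry oracles use ≤20³ grids where brute-force convolution is
exact and fast. OLS uses LAPACK least squares on explicit design matrices;
an RSS below 1e−12·max(1, ‖y‖²) is treated as a perfect fit;
rank-deficient designs (all ages equal) raise rather than returning a
pseudo-inverse solution. Pipeline TSVs are written with `%.10g` floats so
reruns are byte-identical under a fixed seed, and every row carries the
seed and a SHA-256 configuration hash.

## Known limitations

- Right-hemisphere generator defaults mirror the left-hemisphere
  coefficient table (no separate right-hemisphere table was published), so
  hemispheric asymmetries are not represented.
- The printed reference correlations are rounded to 3 decimals; p-values
  recomputed from them via the t transform agree with the printed p-values
  only within the envelope that rounding allows (relative deviations up to
  a few percent), which is the strongest consistency the printed tables
  support.
- Thickness is consumed as a given per-region measure; surface-based
  thickness estimation, cortical segmentation, bias correction, and
  nonlinear registration are out of scope.
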