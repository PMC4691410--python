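# mwfcoupling

Region-wise analysis of the coupling between cortical thickness, cortical
myelin water fraction (MWF), and adjacent white-matter MWF across early
childhood (ages ~1–6 years), together with the synthetic cohorts and
volumetric phantoms needed to exercise every stage without access to cohort
MRI.

Cortical thickness is estimated from T₁-weighted image contrast, and that
contrast is itself a function of white-matter myelination — so are
thickness measurements in young children telling us about cortical
architecture, or merely echoing adjacent myelin? This package implements
the analysis chain that addresses the question:

1. **Adjacent-WM sampling** (`geometry`). Each cortical parcel mask is
   blurred slice-wise with a 2-D Gaussian kernel (FWHM 4 mm,
   σ = FWHM / (2√(2 ln 2))), all non-white-matter voxels are removed, and
   the surviving weights define a weighted mean of the MWF (or T₁) map —
   the parcel's *adjacent white matter* value. Cortical values are plain
   parcel means.
2. **Growth trajectories** (`trajectories`). Per (region, hemisphere,
   measure), OLS fits of `y = a·ln(t) + b` (t = age in days), plus linear
   and quadratic alternatives, compared by
   `BIC = n·ln(RSS/n) + k·ln(n)`; thickness declines and MWF rises
   logarithmically over this age range.
3. **Age-residualized coupling** (`coupling`). Residuals from the
   logarithmic trajectories are correlated per region for the three
   measure pairs; two-sided p-values come from the exact t transform
   `t = r√(n−2)/√(1−r²)` with n−2 df, and family-wise significance from a
   Holm–Bonferroni step-down over the 33 regions of a hemisphere at
   α = 0.05.
4. **Ideal T₁ contrast** (`contrast`). The ideal inversion-recovery signal
   `S(T₁) = 1 − 2·e^(−TI/T₁)` at TI = 950 ms gives a gray/white contrast
   `S(T₁_wm) − S(T₁_gm)` per region, correlated against thickness with the
   same machinery.

The `synthetic` module generates cohorts with the study's structure (134
children, 177 scans with longitudinal repeats ~1 year apart, ages 363–2198
days) whose measures follow published left-hemisphere logarithmic
coefficients and whose residual triples carry the published region-wise
correlation structure; `phantom` builds small parcellated label volumes
with piecewise-constant MWF/T₁ maps for the geometry stage.

## Worked example

```python
from mwfcoupling.pipeline import PipelineConfig, run_pipeline
from mwfcoupling.synthetic import T1Spec

cfg = PipelineConfig(
    seed=42,
    t1=T1Spec(gm_log_slope=-15.0, wm_log_slope=-25.0, noise_sd_ms=20.0),
    out_dir="demo-out",
)
bundle = run_pipeline(cfg)

coef = bundle["coefficients"]
print(coef[(coef.region == "caudal middle frontal") & (coef.hemisphere == "left")])
```

```
               region hemisphere      measure  log_slope  intercept      rss  n_obs
caudal middle frontal       left thickness_mm  -0.229904   4.440430 1.815257    177
caudal middle frontal       left cortical_mwf   0.017147  -0.056265 0.019058    177
caudal middle frontal       left adjacent_mwf   0.022586  -0.038916 0.016676    177
```

The fitted logarithmic slope/intercept recover the generating coefficients
(−0.23 / 4.452 for thickness; 0.022 / −0.035 for adjacent MWF) within
sampling error at 177 scans. The coupling table reports r, p and the
Holm-corrected flag per region and measure pair:

```
       region hemisphere    measure_a    measure_b         r            p   n  significant
supramarginal       left thickness_mm adjacent_mwf -0.259203 4.943895e-04 177         True
supramarginal       left thickness_mm cortical_mwf -0.184713 1.384530e-02 177        False
supramarginal       left cortical_mwf adjacent_mwf  0.470760 3.787077e-11 177         True
```

Across this synthetic cohort the MWF–MWF pair is significant in 62 of 66
regions while the thickness pairs are significant in a minority (26 and 19
of 66) — the qualitative pattern the analysis is designed to expose:
cortical and white-matter myelin develop in lockstep, but thickness is far
from a proxy for either. With T₁ generated independently of thickness, the
contrast–thickness correlation is significant in 0 of 66 regions.

The same pipeline runs from a shell:

```sh
mwfcoupling all --seed 42 --out demo-out
mwfcoupling extract --out phantom-out --save-volumes   # phantom -> regional TSV
```

and accepts real extractions in place of the simulator: any long-format
TSV with `child_id, scan_id, age_days, region, hemisphere, thickness_mm,
cortical_mwf, adjacent_mwf, cortical_t1_ms, adjacent_t1_ms` columns can be
passed via `mwfcoupling report --scans your_scans.tsv`.

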