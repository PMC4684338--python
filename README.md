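# dcepk

Pharmacokinetic analysis of dynamic contrast-enhanced MRI (DCE-MRI) for
predicting and assessing tumor treatment response, aimed at head-and-neck
squamous cell carcinoma imaged with a dual-flip-angle 3D spoiled gradient
echo (SPGR) protocol.

The package implements the full chain from raw dynamic magnitude images to
per-site outcome statistics:

1. **Relaxometry** — pre-contrast T1 and M0 maps from the two-point
   variable-flip-angle SPGR acquisition (2°/15°, closed form).
2. **Concentration conversion** — voxelwise inversion of the SPGR signal
   equation to R1(t) and gadolinium concentration,
   C(t) = (R1(t) − 1/T10)/r1 with r1 = 4.5 s⁻¹mM⁻¹.
3. **Arterial input function** — mean plasma concentration over artery
   voxels, corrected for hematocrit (C_p = C_b/(1 − Hct), Hct = 0.42).
4. **Tofts model fitting** — voxelwise nonlinear least squares of

   C_t(t) = K^trans ∫₀ᵗ C_p(τ) e^(−k_ep (t−τ)) dτ,

   yielding K^trans (min⁻¹), k_ep (min⁻¹) and v_e = K^trans/k_ep, with an
   R² ≥ 0.7 goodness-of-fit filter, plus the model-free area under the
   gadolinium concentration–time curve (AUGC, mM·min).
5. **ROI analysis** — per-site means over the filter-passing voxels,
   volumes in cm³, and pre→post percentage changes.
6. **Outcome statistics** — univariate/stepwise-multivariate logistic
   regression with odds ratios and Wald CIs, paired t-tests, ROC analysis
   with Youden-index thresholds and DeLong AUC confidence intervals,
   diagnostic-performance tables and Fisher's exact test, relating imaging
   parameters to site control (SC) vs site failure (SF).

Because clinical DCE data cannot be redistributed, the package ships a
first-class synthetic module: 4D digital phantoms whose voxels follow known
Tofts kinetics under a parametric population AIF, and simulated per-site
cohorts drawn from published group moments. Every pipeline stage is tested
against these known truths.

## Worked example

Generate a noisy phantom (two tumor-like regions, carotid-like artery
columns), run the full pipeline, and analyse a simulated residual-mass
cohort:

```bash
dcepk simulate --out-dir demo --noise-sigma 0.5 --seed 1 --cohort
dcepk all --config demo/pipeline.yaml --verbose
dcepk outcomes --cohort demo/cohort.csv --out-dir demo/outcomes
```

prints

```
site_id  n_voxels  n_valid  volume_cm3  mean_ktrans  mean_kep  mean_ve  mean_augc  analyzable
tumor_a        72       72    0.852019     0.367662  0.668812 0.549687   2.419494        True
tumor_b        48       48    0.568013     0.327921  0.639203 0.513014   2.240643        True
pct_change_augc: AUC 0.778 (95% CI 0.609-0.947), optimal threshold 12.11
sens 64.3%  spec 89.5%  acc 78.8%  ppv 81.8%  npv 77.3%  Fisher p 0.00226
```

The phantom's ground truth is K^trans = 0.37/0.33 min⁻¹ and
k_ep = 0.67/0.64 min⁻¹ for the two regions: the ROI means recover it to
within ~1% at this noise level, and every voxel passes the R² filter
(`n_valid == n_voxels`). The cohort lines show the outcome layer at work on
one simulated 33-site cohort: the area under the ROC curve for the
percentage change in AUGC (SF = positive class), the Youden-optimal
threshold, and the diagnostic performance of calling sites above that
threshold failures.

The same stages are available as library functions (`dcepk.relaxometry`,
`dcepk.kinetics`, `dcepk.roi`, `dcepk.stats`, `dcepk.synthetic`,
`dcepk.pipeline`) for use without the CLI.

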