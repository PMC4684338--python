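# Methods

## Signal model and relaxometry

All acquisitions are modelled as spoiled gradient echo (SPGR) at steady
state:

    S = M0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR/T1).

Perfect spoiling and a uniform transmit field are assumed; no B1 correction
is applied. With exactly two flip angles (2° for the pre-contrast
calibration scan, 15° for the dynamic series) the linearisation
y = S/sin α vs x = S/tan α has slope E1 and intercept M0(1 − E1), so T1 and
M0 are solved in closed form per voxel — an iterative fit would add nothing
with two points. Voxels whose implied E1 falls outside (0, 1), or whose T1
falls outside plausibility bounds of 50–5000 ms, are flagged invalid and
carried as NaN rather than clipped; no spatial smoothing or regularisation
is applied to the maps.

The default protocol constants are TR = 4.0 ms, TE = 1.0 ms, flip angles
2°/15°, temporal resolution 2.59 s/dynamic, 185 dynamics, injection 6 s
after the start of the dynamic series, 4 mm slices on a 128×128 matrix.
Note the printed per-frame spacing times the frame count (2.59 s × 185 =
479.15 s) is what the code uses as the scan duration.

## Concentration conversion

The pre-contrast frames are those acquired strictly before the injection
command — floor(6/2.59) = 2 frames at the default timing. Their mean,
together with the voxel's T10, calibrates M0 at the dynamic flip angle;
the SPGR equation is then inverted frame by frame to R1(t) and

    C(t) = (R1(t) − 1/T10) / r1,    r1 = 4.5 s⁻¹ mM⁻¹.

A voxel is excluded from analysis when any frame's signal leaves the
invertible range (E1 ∉ (0, 1); e.g. signal at or above the SPGR ceiling
M0·sin α). Baseline frames yield C ≈ 0 by construction.

## Arterial input function

The plasma curve is the mean whole-blood concentration over the artery
voxels divided by (1 − Hct) with Hct = 0.42. Blood T1 for the conversion is
taken from the same dual-angle T1 map at the artery voxels (no fixed
literature value), which keeps the phantom round trip exact. No bolus
dispersion or arrival-delay correction between artery and tissue is
applied.

## Tofts model fitting

Tissue curves follow the single-compartment Tofts model

    C_t(t) = Ktrans ∫₀ᵗ C_p(τ) e^(−kep (t−τ)) dτ,

parameterised by (Ktrans, kep) with ve = Ktrans/kep derived, so the ratio
identity holds exactly for every fit. Rates are in min⁻¹; time grids are in
seconds and converted at the model boundary. The convolution is discretised
by linear interpolation of C_p on each sampling interval with exact
integration of (linear × exponential), implemented as a first-order
recursion (an IIR filter on uniform grids); for constant C_p this
reproduces the closed-form step response to machine precision, and `expm1`
guards the small-kep·dt regime.

The least-squares fit uses scipy's trust-region-reflective solver with
bounds Ktrans ∈ (10⁻⁴, 5] min⁻¹ and kep ∈ (10⁻⁴, 10] min⁻¹. Initialisation
is a deterministic coarse search over 25 log-spaced kep values in
[0.01, 10] min⁻¹, profiling Ktrans analytically at each node (the model is
linear in Ktrans given kep), so fitting is reproducible without random
multistarts. R² = 1 − SS_res/SS_tot is reported per voxel; a flat curve has
undefined R² and is flagged non-converged. Voxels with R² below the
threshold (default 0.7) or a failed fit stay in the maps but are excluded
from ROI statistics — the conservative reading of an R²-based fit filter.
Fitted ve is allowed up to Ktrans/kep of the bound ratio; unusually high
values are retained, not clipped.

AUGC is the trapezoidal integral of the concentration curve over the whole
acquisition, reported in mM·min. (A label of mM·s sometimes appears for
this quantity in the clinical literature, but magnitudes of ≈2–3 over a
~460 s acquisition are only consistent with minute-based integration, so
minutes are used throughout.)

## ROI analysis

Site summaries are arithmetic means over the voxels passing the R² filter;
a site with fewer than 5 usable voxels is flagged unanalyzable (the
analogue of residual masses too small or necrotic to analyse). Volume is
voxel count × voxel volume in cm³ from the same contour used for the DCE
analysis. Percentage change is 100·(post − pre)/pre and is undefined for
pre = 0.

## Outcome statistics

* Univariate logistic regression (statsmodels MLE) reports the slope, odds
  ratio per unit, Wald 95% CI and Wald p. Complete separation is flagged
  and the CI reported as unbounded; a constant predictor returns OR = 1.
* Stepwise multivariate selection is forward entry at p < 0.05 with
  backward removal at p ≥ 0.10, both by likelihood-ratio tests (the common
  stepwise-logistic defaults); selected terms are refit with the stated
  confounders to give adjusted odds ratios. An empty selection is a valid
  outcome, not an error.
* ROC analysis computes the AUC as the Mann–Whitney probability from
  midranks (exactly the trapezoidal area under the empirical curve on
  tie-free data), a DeLong-variance 95% CI, and an optimal threshold
  maximising Youden's J = sensitivity + specificity − 1 — the standard
  operationalisation of weighting sensitivity and specificity equally.
  Candidate thresholds are midpoints between adjacent distinct scores;
  J ties resolve to the lowest candidate. Predictions are strict
  inequalities ("score > threshold" calls a failure).
* Diagnostic tables report sensitivity, specificity, accuracy, PPV and NPV
  as percentages; undefined ratios are NaN, never zero.
* Fisher's exact test uses the two-sided minimum-likelihood convention
  (sum of hypergeometric probabilities no larger than the observed
  table's), matching SAS/R.
* The paired t-test is two-sided on post − pre differences; zero-variance
  differences are flagged degenerate.

Sites are treated as independent observations even when a patient
contributes several, and no multiple-testing correction is applied across
parameters.

## Synthetic data

The phantom generator emulates the acquisition end to end: tissue voxels
follow `tofts_forward` of their region's ground truth under a parametric
population AIF; artery voxels carry the whole-blood signal
C_b = C_p·(1 − Hct); a matching 2° pre-contrast volume supports T1 mapping;
background voxels are non-enhancing tissue. Noise is additive Gaussian on
the magnitude signal (a Rician option exists; at clinical SNR the two are
practically indistinguishable and Gaussian keeps the oracles simple), with
every random draw derived from an explicit seed.

The AIF is parametric because manual arterial voxel selection is not
reproducible and closed forms give analytic oracles. Three forms are
available: a pure biexponential decay, the default biexponential with an
8 s linear upslope (continuous at onset), and a Parker-type mixture. The
default amplitudes (a1 = 1.4 mM, m1 = 1.0 min⁻¹; a2 = 0.55 mM,
m2 = 0.05 min⁻¹) were set once so that a tissue curve at typical
head-and-neck tumor kinetics (Ktrans 0.37 min⁻¹, kep 0.67 min⁻¹)
integrates to ≈ 2.4 mM·min over the default acquisition, the reported
scale for such tumors. Bolus onset is 12 s (injection command at 6 s plus
a nominal 6 s transit); the true injection-to-carotid delay is a free
parameter, not calibrated to any study.

The default phantom places two homogeneous tumor-like boxes
(Ktrans 0.37/0.33 min⁻¹, kep 0.67/0.64 min⁻¹, T1 1100/1000 ms) and two
2×2-voxel artery columns (T1 1650 ms) in a small grid. Test problem sizes —
10×10×4 to 12×12×4 grids giving 120–224 tumor voxels, SNR 50 on the
baseline signal for recovery studies, 1000–2000 replicate cohorts for the
ROC simulation — were chosen as the smallest sizes at which the sampling
error of each check is well below its tolerance.

The cohort generator draws per-site parameter values as independent
normals with per-group (site failure / site control) means and SDs, with
group sizes 14/19 and the published residual-mass moments as the default.
It reproduces group-level moments only: it does not model within-patient
correlation of multiple sites, correlations between parameters, or the
truncation/skew of real physiological distributions. Passing tests
therefore demonstrate correctness of the estimators and statistics under
the stated group-moment model, not robustness to those real-data features.

What the phantoms do not emulate: patient motion (registration is a no-op
hook), B1 inhomogeneity, slice-profile effects, bolus dispersion,
partial-volume mixing at region borders, and physiological heterogeneity
within regions. Recovery results on phantoms are accordingly a validation
of the numerics and plumbing, not of robustness to acquisition artefacts.

## Numerical and degenerate-input choices

* Closed-form dual-angle T1: invalid voxels are excluded, never imputed.
* Grid-based fit initialisation makes the voxel fit deterministic for
  identical inputs; the optimizer tolerance is xtol = 1e-10.
* All-zero or non-finite concentration curves yield flagged non-converged
  voxel results; fits require ≥ 10 time points.
* AUGC requires ≥ 2 time points; the trapezoid rule is used verbatim.
* Empty ROI intersections raise a typed error that the pipeline converts
  into an "unanalyzable" site row rather than a crash.

## Known limitations

* The two-point T1 method propagates baseline noise into concentration
  scale; with only two pre-contrast frames the calibration noise is the
  dominant error source at low SNR.
* The standard Tofts model omits the intravascular plasma term; strongly
  vascularised voxels will show inflated ve, and fitted ve near or above 1
  is possible and retained.
* DeLong CIs and Wald ORs are asymptotic; at n = 33 sites they are rough,
  which matches the width of the intervals they produce.
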