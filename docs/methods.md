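# Methods

## The function model

The core quantity is an exponential regression of ICG plasma disappearance
rate on two imaging measurements: the T1 reduction rate RR (percent
shortening of the liver T1 relaxation time from pre-contrast to the
hepatobiliary phase of a Gd-EOB-DTPA examination) and a liver volume V in
mL,

    f(RR, V) = scale · exp(a · RR) · exp(b · V / u),

with `scale = 0.84 %/min`, `a = 0.038` per percent RR, `b = 0.045` per
`u = 100 mL`. Evaluated with the total functional liver volume LV this is
eLF; with the future remnant volume rLV = LV − resection volume it is
erLF, the preoperative prediction of postoperative clearance. The
coefficients are taken as given from the prior volume-assisted relaxometry
calibration and are not re-fitted here.

**Volume unit.** The volume coefficient is defined per 100 mL
(`ModelCoefficients.vol_unit_ml`, configurable). A per-mL coefficient of
0.045 would put ~72 in the exponent for a normal 1609 mL liver and yield
function estimates around 10³⁰, incompatible with the %/min scale the
model lives on; per 100 mL, the estimate for cohort-mean inputs
(RR 58.4 %, 1609 mL) is 15.94 %/min, consistent with observed mean PDR
values. The unit is an explicit coefficient so other conventions can be
expressed without touching code, and every pipeline run logs the
interpretation in its header.

**Classification.** erLF is partitioned with the postoperative ICG
cut-offs: dysfunction (PLDF) strictly below 10 %/min, normal (PNLF)
strictly above 17 %/min, "at risk" on the closed interval [10, 17]. The
closed middle interval is a deliberate convention: the outer classes are
defined by strict inequalities, so boundary values belong to the middle
class. Preoperatively, dysfunction (LDF) is PDR < 17 %/min *or*
R15 > 8 % — again strict, so the boundary pair (17, 8) is classified as
normal. Under the monoexponential model the two preoperative cut-offs are
nearly equivalent (R15 at PDR 17 is 100·e^(−2.55) = 7.81 %), so the OR
rarely disagrees with the PDR criterion alone.

## ICG kinetics

A bolus of ICG decays monoexponentially; `fit_monoexponential` performs
unweighted ordinary least squares on log-concentration versus time. The
negative slope is the decay constant k, PDR = 100k (clamped at 0 for
non-decaying curves), the intercept back-extrapolates the initial
concentration c0, and R15 = 100·e^(−15k) is the *modelled* retention at 15
minutes rather than a raw sample — noise-robust and consistent with the
transformation that defines PDR. Whether bedside devices weight the fit is
not public; unweighted is the deterministic, reproducible choice.

## Volumetry

Volumes are voxel counts times the voxel volume from the grid spacing of a
NIfTI label mask (labels: remnant 1, resected 2, lesion 3, vessel 4).
Functional liver volume counts only remnant + resected; lesion and vessel
labels are excluded by construction. No partial-volume weighting is
applied: volumes are exact at voxel granularity, and the invariants
(additivity over disjoint roles, linear scaling with spacing) are tested.
Interactive segmentation itself is out of scope — the package consumes
finished label maps.

## Outcome rules

Acute postoperative dysfunction: on any postoperative day 3–7, bilirubin
above 1.0 mg/dL *and* above the preoperative value, or INR above 1.15 and
above the preoperative value (the "increase" qualifier resolves the
otherwise directionless bilirubin cut-off). Severe failure: the 50/50
criterion — bilirubin > 50 µmol/L (= 2.92 mg/dL at 584.66 g/mol) with
INR > 1.7 on the same day — or peak bilirubin > 7 mg/dL in the window.
Severe failure implies acute dysfunction by definition and the flag object
enforces the implication. Days outside the window are ignored; a series
with no coverage of the window yields negative flags with a warning.

## Diagnostic evaluation

Confusion matrices, the five summary metrics (ratios reported as
not-available on zero denominators, never 0), and ROC-AUC via pairwise
concordance (delegated to scikit-learn; a brute-force pairwise oracle
verifies it in the tests). Orientation is an explicit, mandatory flag —
function scores predict dysfunction at *low* values, and a silent
inversion would reflect the AUC around 0.5.

`reconstruct_confusion` inverts a published performance table: given class
sizes and 1–4 metrics printed at two decimals, it enumerates all integer
(tp, tn) pairs and returns the matrices whose metrics round back (half-up
at printed precision) to the anchors, reporting non-uniqueness and, via
`rounding_mismatches`, any metric whose recomputed rounding disagrees with
a printed figure. Applied to the 19-positive/52-negative setting of the
model-comparison table this recovers (tp=10, tn=40) for the
preoperative-ICG row and (tp=10, tn=46) for the erLF row, and surfaces two
irreducible rounding slips in the printed row: specificity 46/52 = 0.8846
prints as 0.88 (not 0.89), and PPV 10/22 = 0.4545 prints as 0.45 (not
0.46) — no integer matrix consistent with the other anchors can produce
those printed values.

The Mann–Whitney U test uses midranks for ties; the two-sided p-value is
enumerated exactly over all group assignments when n1+n2 ≤ 12 (≤ 924
arrangements; "as or more extreme" measured by distance of U from its
null mean), and otherwise uses the normal approximation with tie and
continuity corrections. The switch point bounds enumeration cost while
keeping the exact branch for the small-sample comparisons where the
approximation is weakest.

## Survival analysis

The univariable Cox model maximises the Breslow partial likelihood by
Newton–Raphson with analytic gradient and Hessian (start β = 0, step
tolerance 1e-8, max 50 iterations, covariate centred for numerical
stability — the estimate is translation-invariant). The standard error
comes from the observed information; the 95 % CI is Wald on the log scale.
Breslow tie handling is fixed and documented: with continuous covariates
and near-continuous times the Efron difference is negligible, and an
independent library fit cross-checks the estimate in the tests. The
covariate is continuous erLF per unit — the only reading under which a
hazard ratio slightly below 1 per unit is meaningful.

Kaplan–Meier curves use the product-limit estimator with exact rational
accumulation of ∏(1 − d/n), so that in the uncensored case the
telescoping identity S(t) = #{times > t}/n holds bit-exactly in the float
output. Censored times reduce the risk set without steps. Stratified
curves (one per erLF class) omit empty strata with a warning.

## Synthetic cohort generator

No patient-level data are distributable, so the generator emulates the
*structure* the analysis assumes, with an explicit latent model:

| parameter | default | unit | role |
|---|---|---|---|
| n | 71 | patients | study-sized cohort |
| t1_plain_mean / sd | 751.9 / 99.7 | ms | pre-contrast T1 |
| rr_mean_nlf / rr_mean_ldf | 61.3 / 51.9 | % | status-specific RR means |
| rr_sd | 10.0 | % | pooled RR spread |
| lv_mean / lv_sd | 1609 / 443 | mL | lognormal, moment-matched |
| ldf_fraction | 22/71 | — | dysfunction prevalence |
| resection_fractions | 0.10/0.20/0.50 @ 21:14:36 | — | surgery mix (mean resected ≈ 508 mL) |
| pdr_link_noise_sd | 3.0 | %/min | function→clearance noise |
| survival_log_hazard_per_erlf | ln 0.87 | per %/min | survival link |
| baseline_hazard_per_day | 4.5e-3 | /day | median death ≈ 3 y at mean erLF |
| censor_rate | 1/3000 | /day | independent censoring |
| followup_cap_days | 1800 | days | administrative truncation |

Pipeline: Bernoulli LDF status → RR from the status normal → T1HBP
*derived* from RR (so the relaxometry equation is exact on every record)
→ lognormal LV → resection fraction by weighted surgery type →
preoperative PDR = eLF + noise and postoperative PDR = erLF + noise
(floored at 0.1 %/min), R15 = 100·e^(−0.15·PDR) + noise → elevated
bilirubin/INR arcs over POD 3–7 for dysfunction courses → exponential
survival with log-hazard linear in erLF. Everything is driven by one
seeded generator: identical (params, seed) give byte-identical cohorts.

What the generator does *not* emulate: inter-variable correlations beyond
the single latent dysfunction indicator, lesion-type covariates,
non-proportional hazards, informative censoring, measurement drift between
scanners, or any imaging content — only summary structure. Passing tests
therefore demonstrate correctness of the computational chain under the
assumed model, not clinical performance on real patients. Because the
postoperative PDR is generated *from* erLF, synthetic discrimination
metrics (AUC ≈ 0.95 at the default noise) are optimistic relative to
observed cohorts; the zero-noise configuration degenerates to perfect
agreement and is used as an end-to-end identity check.

## Problem sizes and numerical choices

Moment and calibration checks use n = 5000 (3-standard-error bands);
CI-coverage simulations use 100 replicates of n = 1000, sized so the
binomial uncertainty on a 95 % coverage estimate (±2 percentage points)
stays well inside the accepted [0.90, 0.99] band. Cohort CSVs are written
with `%.17g` and read with round-trip float parsing so write∘read is the
identity on every IEEE double. Publication-style rounding is half-up at
the printed number of decimals, implemented with decimal arithmetic on the
shortest float representation (no double rounding).

## Known limitations

* The 0.84/0.038/0.045 coefficients are external inputs; the package does
  not refit them, and their intercept unit (%/min) is an assumption.
* Only label-based vessel/lesion exclusion is supported, no thresholding.
* No multivariable Cox, proportional-hazards diagnostics, or log-rank
  test; no DeLong comparison of correlated AUCs.
* The synthetic generator's latent model is one of many consistent with
  the targeted marginal moments.
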