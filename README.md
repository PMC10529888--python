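# remliver — volume-assisted estimation of remnant liver function

Liver resection can cure tumours and kill patients: remove too much
functioning parenchyma and the remnant cannot sustain life ("small-for-size
syndrome"). Planning therefore needs a *preoperative* estimate of the
function that will remain *after* surgery. `remliver` implements such an
estimate from gadoxetic-acid (Gd-EOB-DTPA) enhanced MR relaxometry combined
with liver volumetry, evaluates it against the indocyanine-green (ICG)
clearance reference standard, and quantifies its prognostic value for
survival. It is aimed at researchers in hepatobiliary imaging and clinical
biostatistics who want a tested, scriptable implementation of the whole
analysis chain.

## The model

Functioning hepatocytes take up Gd-EOB-DTPA, shortening the tissue T1
relaxation time between the pre-contrast map (T1plain) and the
hepatobiliary phase (T1HBP). The reduction rate

    RR = (T1plain − T1HBP) / T1plain × 100 %

is a regional surrogate of hepatocyte function. Combined with the
functional liver volume LV (from a segmentation mask that excludes vessels
and lesions), liver function on the ICG-PDR scale is estimated as

    eLF  = 0.84 · exp(0.038 · RR) · exp(0.045 · LV / 100 mL)

and the *remnant* function after a planned resection by substituting the
future remnant volume rLV = LV − resection volume:

    erLF = 0.84 · exp(0.038 · RR) · exp(0.045 · rLV / 100 mL)

(the volume coefficient applies per 100 mL; see `docs/methods.md`).
Patients are classified with the same cut-offs as the postoperative ICG
test: erLF > 17 normal, 10–17 at risk, < 10 dysfunction. The package also
contains the ICG kinetics (monoexponential PDR/R15 fitting), NIfTI
volumetry, diagnostic-test evaluation (confusion matrices, ROC-AUC,
Mann–Whitney U, exhaustive reconstruction of published 2×2 tables),
univariable Cox and Kaplan–Meier survival analysis, and a seeded
synthetic-cohort generator that reproduces the statistical structure of a
hepatectomy collective for end-to-end testing.

## Worked example

```python
import remliver as rl

rr   = rl.reduction_rate(rl.T1Pair(t1_plain=751.9, t1_hbp=310.2))
elf  = rl.estimated_function(rr, 1609.0)   # whole liver
erlf = rl.estimated_function(rr, 1101.0)   # remnant after a 508 mL resection
print(f"RR = {rr:.2f} %  eLF = {elf:.2f} %/min  erLF = {erlf:.2f} %/min  "
      f"class = {rl.classify_erlf(erlf).value}")

cfg = rl.RunConfig(generator=rl.GeneratorParams(n=71, seed=1), seed=1)
rep = rl.run_pipeline(cfg)
print(rep["metrics"].round(3).to_string(index=False))
cox = rep["cox"]
print(f"Cox on erLF: HR {cox.hr:.3f} "
      f"(95% CI {cox.ci_low:.3f}-{cox.ci_high:.3f}, p={cox.p_value:.4g})")
```

prints

    RR = 58.74 %  eLF = 16.15 %/min  erLF = 12.85 %/min  class = at_risk
        model  sensitivity  specificity   ppv   npv  accuracy   auc
    preop_icg        1.000         0.46 0.438 1.000     0.620 0.890
         erlf        0.857         0.92 0.818 0.939     0.901 0.954
    Cox on erLF: HR 0.838 (95% CI 0.777-0.904, p=4.828e-06)

The first line scores a typical patient: a 58.7 % T1 reduction with a
1609 mL liver gives an estimated whole-liver function of 16.2 %/min;
removing 508 mL drops the estimate to 12.9 %/min — an "at risk" remnant.
The table evaluates two predictors of postoperative dysfunction
(postoperative PDR < 10 %/min) on a 71-patient synthetic cohort: the
imaging-based erLF classifier and the preoperative ICG classification.
The Cox line shows that each additional %/min of estimated remnant
function lowers the death hazard by ~16 % in this simulated cohort.

The same stages are available as a CLI:

    remliver simulate -n 71 --seed 1 -o cohort.csv
    remliver score cohort.csv -o scored.csv
    remliver evaluate scored.csv
    remliver survival scored.csv -o km.csv
    remliver volumes mask.nii.gz

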