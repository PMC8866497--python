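# textconfound

Uncover interpretable potential confounders from clinical free text and
evaluate them with propensity-adjusted survival analysis.

Retrospective treatment comparisons from electronic medical records are
routinely biased by treatment selection: the patients who get surgery are
not the patients who get radiation. Structured registry fields (age, race,
stage, ...) rarely capture the clinical judgment behind the choice — but
the pre-treatment notes often do. `textconfound` is for biostatisticians
and clinical-informatics researchers who want to (1) turn notes into
*interpretable* term covariates a clinician can audit, (2) screen them for
potential confounders, and (3) see how the treatment hazard ratio moves
once they are adjusted for.

## The method

For patient *i* with covariates *X_i* (structured block + bag-of-words
TF-IDF block from pre-treatment notes), treatment *W_i* ∈ {0, 1} and
right-censored survival (*Y_i*, *E_i*):

1. **Dual-Lasso screening.** Fit an L1-penalized logistic model
   *W ~ X* and an L1-penalized Cox model *(Y, E) ~ X*, each with 10-fold
   cross-validation over a λ path. At the chosen penalty (`lambda.1se`,
   the sparsest model within one SE of the CV minimum, or `lambda.min`)
   take the **intersection of the two supports**: covariates predictive of
   both treatment and outcome are the potential confounders.

2. **Propensity-adjusted hazard ratios.** With propensity scores
   e(X) = P(W = 1 | X) from the best-balanced of {logistic, gradient
   boosting, random forest}, estimate the treatment HR under the Cox model

       h(t | X) = h0(t) · exp(b_W · W + Σ_j b_j X_j)

   three ways: 1:1 nearest-neighbor **matching** on e(X); **IPTW** with
   stabilized weights w = W + (1 − W)·e/(1 − e); and **multi.coxph**, an
   IPTW-weighted multivariate Cox model (doubly robust). Each runs on
   three covariate sets — structured, intersect, struct+intersect — and
   reports ΔHR, the shift from the structured-only baseline.

Real EMR corpora are private, so the package ships a synthetic EMR
generator (`textconfound.synthetic`) that plants text-borne confounders
with known effects, giving every claim above a testable ground truth.

## Worked example

`examples/04_estimate_hazard_ratios.py` simulates 1000 patients where two
note terms (`bladder`, `copd`) raise both the odds of surgery and the
death hazard while the true treatment HR is exactly 1, then runs the full
pipeline:

```
comparison: surgery vs radiation
intersection: ['struct:clinical_stage', 'struct:patient_age', 'text:bladder', 'text:copd']
estimator    covariates             HR           95% CI       p   ΔHR   shift
iptw         intersect            1.13 [ 0.95,  1.34]   0.158  0.26   18.6%
iptw         struct+intersect     1.15 [ 0.97,  1.35]   0.114  0.24   17.4%
iptw         structured           1.39 [ 1.17,  1.64]   0.000    -       -
matching     intersect            1.19 [ 0.99,  1.43]   0.061  0.31   20.9%
matching     struct+intersect     1.24 [ 1.03,  1.48]   0.024  0.27   17.9%
matching     structured           1.51 [ 1.25,  1.81]   0.000    -       -
multi.coxph  intersect            1.22 [ 1.01,  1.46]   0.036  0.22   15.5%
multi.coxph  struct+intersect     1.22 [ 1.02,  1.47]   0.031  0.21   14.9%
multi.coxph  structured           1.44 [ 1.22,  1.70]   0.000    -       -
```

Reading it: adjusting for structured covariates alone leaves a spurious,
"significant" harm estimate for surgery (HR 1.39–1.51, p < 0.001) that is
pure treatment-selection bias. The dual-Lasso intersection recovers both
planted terms, and every estimator shifts toward equipoise (ΔHR ≈
0.2–0.3, 15–21 % of the baseline) once they are adjusted for — the
direction of the known truth, HR = 1.

The other examples walk the individual capabilities: cohort simulation
(`01`), note featurization (`02`), confounder selection (`03`), and
multi-seed recovery validation (`05`). A thin CLI mirrors the pipeline
(`textconfound simulate|featurize|select|estimate|report|validate`); see
`textconfound --help`.

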