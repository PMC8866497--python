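# Methods

`textconfound` implements a workflow for retrospective treatment
comparisons from electronic medical records (EMR): featurize pre-treatment
clinical notes into interpretable term covariates, select *potential
confounders* — covariates predictive of both treatment assignment and
survival — and re-estimate the treatment hazard ratio (HR) under three
propensity-adjusted estimators. Because real EMR corpora are private, the
package ships a synthetic EMR generator with planted, text-borne
confounding; every statistical guarantee the test suite asserts is a
property of the method evaluated against that generator's known ground
truth.

## Data model

A patient record carries structured registry fields (age, gender, race,
ethnicity, clinical/pathological stage, tumor grade, diagnosis year),
dated free-text notes, treatment records (modality, start day), and a
right-censored survival outcome `(Y, E)` in days since diagnosis.
A comparison is a pair of treatment groups; `W = 1` denotes the treated
group of the comparison.

### Cohort rules

* Group assignment follows the *first* treatment received; prostate
  patients without treatment records form the active-monitoring group,
  NSCLC patients without treatments are excluded. Equal surgery/radiation
  start days raise an error: there is no defensible tie rule, and silent
  choices would be invisible in downstream estimates.
* Patients must survive ≥ 183 days (six months, boundary inclusive) past
  diagnosis — a landmark filter against immortal-time bias.
* Only notes dated at least 60 days (prostate) / 30 days (NSCLC) before
  the treatment start date are used, so covariates never encode the
  treatment choice itself; the boundary note is kept. Patients need at
  least one usable note. Monitoring patients have no treatment date and
  contribute all notes.
* Missing clinical stage is imputed by a seeded random forest trained on
  patients with both stages (features: age bucket, pathological stage,
  diagnosis year, grade). Missing grade is imputed with the median
  observed grade plus a `grade_unknown` indicator.

### Structured block

Age enters as an ordinal bucket index (≤49, 5-year bands 50–84, ≥85);
race as white/api/black one-hots (unknown ⇒ all zeros); ethnicity as a
single `hispanic` indicator; stage and grade as ordinals 1–4;
diagnosis year as a continuous covariate. Prostate: 9 columns
(age, 3 race, hispanic, stage, year, grade, grade_unknown). NSCLC: 7
(stage and grade dropped — the cohort is restricted to clinical stage I —
and `male` added). All columns are z-scored (sample SD); constant columns
are set to zero and logged, and are excluded from adjustment sets.

## Text featurization

1. **Segmentation** on clinical field labels (ALL-CAPS token(s) + colon),
   tab runs, and sentence punctuation; labels are removed.
2. **Boilerplate**: the first and last two sentences of each document are
   trimmed, and sentences matching configurable location/physician
   patterns (e.g. `medical center`, `M.D.`) are dropped.
3. **Negation filter**: a sentence with fewer than 15 words (whitespace
   tokens after punctuation stripping) containing a negation term (`no`,
   `denies`, `does not`, `none`; token/phrase match, case-insensitive) is
   removed — this is what keeps "No history of smoking." from producing a
   `smoking` covariate. Long negated sentences are kept: the negated
   concept is usually incidental there. The filter is idempotent.
4. **Entity extraction** is a dictionary matcher: tokens are lowercased,
   punctuation-stripped, lemmatized by a suffix-rule + exception-lookup
   lemmatizer (plural folding; `-ing`/`-ed` stripped only when the stem is
   a known term), folded through a synonym map (`hx → history`,
   `fu → follow-up`, ...), filtered against stopwords, and kept only if
   they appear in the configured term dictionary. The shipped dictionary
   is small and user-replaceable; the interpretability of the output rests
   entirely on surface terms.
5. **TF-IDF**: candidate n-grams (unigrams, optionally bigrams) are ranked
   by total corpus frequency; any n-gram whose document frequency
   *reaches* the ceiling (default 0.7; a ceiling of exactly 1.0 disables
   the filter) is excluded; the top-K survivors form the vocabulary.
   Cells are `tf × idf` with the smoothed idf `ln((1+N)/(1+df)) + 1` and
   per-patient L2 normalization — the dialect is fixed so tests are
   bit-stable. Presets: K = 500 unigrams (prostate-like) or K = 1000
   uni+bigrams with the 0.7 ceiling (NSCLC-like); the test suite uses
   K = 25 against a 25-term dictionary.

## Confounder selection

Two L1-penalized models are fit on the identical scaled covariate matrix:
logistic regression for `W` and a Cox proportional-hazards model for
`(Y, E)` (Breslow ties inside the penalized fit). Each uses a 100-point
geometric λ grid (ratio 1e−3 for n > p, else 1e−2) and seeded 10-fold CV;
the CV error is held-out binomial deviance (treatment) or held-out Breslow
partial-likelihood deviance per event (outcome; the "basic" CV flavor).
`lambda.min` minimizes the CV error; `lambda.1se` is the largest λ within
one standard error of that minimum; ties break toward larger λ (sparser).
The **intersection** of the two supports at the chosen policy is the set
of potential confounders. When `lambda.1se` yields no text-derived
intersection the result carries a diagnostic suggesting `lambda.min`
(the documented fallback for under-powered comparisons). A warning fires
when intersection + structured covariates exceed events/10 (the 1-in-10
rule of thumb). Unpenalized refits on the selected support provide the
displayed coefficients.

The logistic path is solved per-λ with liblinear (`intercept_scaling` 50
so the intercept penalty is negligible); on a 100-point grid its supports
agreed with saga at 99/100 λ values in a direct check, at a quarter of the
cost. The Cox path comes from coordinate-descent elastic net with
`l1_ratio = 1`.

## Hazard-ratio estimation

All Cox models use Efron tie handling, Newton–Raphson to precision 1e−12,
and a robust (sandwich) variance with weights treated as fixed. Propensity
scores `e(X)` come from logistic regression, gradient boosting, or a
random forest; scores are cross-fitted (2-fold, seeded; switchable to
in-sample) so balance diagnostics are not flattered by overfitting, then
clipped to [0.01, 0.99] for positivity. The learner with the smallest
mean absolute post-weighting standardized mean difference is selected,
subject to overlap (no arm may have > 5 % of scores clipped); ties prefer
logistic > boosting > forest.

* **matching** — 1:1 greedy nearest-neighbor matching on the score,
  without replacement, processing in descending score order, then a
  univariate Cox model on the matched sample. The minority arm is always
  matched into the majority pool: when treated units outnumber controls
  (the common regime in surgery-heavy cohorts) the naive treated→control
  greedy scheme exhausts the control pool and retains precisely the
  highest-propensity treated patients; in a 50-seed synthetic sweep that
  variant achieved *zero* bias reduction, while minority-into-majority
  matching restores it. No caliper by default (configurable).
* **IPTW** — univariate Cox model with stabilized weights
  `w = W + (1 − W) · e/(1 − e)`: treated weight 1, controls their
  propensity odds, reweighting controls to the treated population.
* **multi.coxph** — multivariate Cox model on `[W, covariates]`, also
  IPTW-weighted: doubly robust in the sense that consistency needs only
  one of the two models to be right.

Each estimator runs on three covariate sets — `structured`,
`intersect`, `struct+intersect` — and each adjusted estimate is
summarized by `ΔHR = |HR_baseline − HR_adjusted|` against the same
estimator's structured baseline, with `percent = 100·ΔHR/HR_baseline`
(the denominator fixed by the worked example pairs
2.51→1.54 = 38.6 % and 0.39→0.54 = 38.5 %), rounded to 2/1 decimals at
the reporting layer only, and labelled "toward equipoise" when the
adjusted HR is closer to 1. Per-covariate HR tables (univariate +
multivariate Wald tests) are *unweighted*. CIs inside matched samples are
robust but not pair-clustered.

## Synthetic EMR generator

Latent condition indicators `Z_j ~ Bernoulli(prevalence_j)` drive both
models: treatment `W ~ Bernoulli(sigmoid(b0 + Σ γ_t,j Z_j + structured
effects))` and survival `T ~ Exponential(h0 · exp(Σ γ_y,j Z_j +
structured effects + b_w W))`. The exponential baseline gives closed-form
sampling and satisfies proportional hazards by construction. Censoring is
independent exponential with its rate solved numerically (Brent) so the
expected censored fraction hits `censoring_rate`. Notes are
sentence-templated English: two boilerplate sentences at head and tail, a
field label, one affirmative sentence per active condition, Poisson noise
terms, and (with configurable probability) a short negated mention of an
*inactive* condition that the negation filter must discard. Some grades
(5 %) and clinical stages (10 %) are masked to exercise imputation.

Default conditions, chosen once as a plausible desk-scale analogue of a
localized-cancer registry cohort: n = 1000; 25-term vocabulary; two
planted confounders (`bladder`, prevalence 0.35; `copd`, 0.30) with
γ_t = γ_y = 1; structured effects age (0.3, 0.5) and stage (0.2, 0.3) on
standardized scales; treatment intercept 0; baseline hazard 1/2000 per
day; true treatment log-HR 0 (equipoise, so any estimated effect is pure
confounding); 20 % censoring; 3 notes/patient; treatment start uniform on
days 90–150; mean 2 noise terms per note; negated-mention rate 0.3. The
corpus statistics (note length, term frequencies) are not calibrated to
any real corpus — they are configuration, not measurement.

What the generator does **not** emulate: real clinical language and its
ambiguity, context-dependent negation scope, longitudinal
vitals/labs/codes, informative censoring, non-proportional hazards, and
confounders invisible in text. Passing tests therefore demonstrate that
the pipeline recovers term-mediated confounding under its own generative
assumptions — not that it would uncover every confounder in real notes.

## Validation problem sizes

The packaged validation uses desk-scale runs: selection recovery and
bias reduction over 50 seeds at n = 1000 (planted terms enter the
intersection in ≥ 90 % of seeds; `struct+intersect` beats `structured`
on |log HR − b_w| in ≥ 90 % of seeds for each estimator); all-noise
cohorts give mean intersection size ≤ 1; and with b_w = 0 the adjusted
95 % CIs cover HR = 1 in ≥ 90 % of 200 seeds at n = 500 (propensity fit
on ground-truth indicators, isolating estimator calibration from
selection noise). Oracle equivalences are exact: Cox vs brute-force
partial-likelihood maximization (1e−6), Wald p-values vs the normal
closed form (1e−10), matching vs an independent greedy re-implementation
on all 4+4 arm assignments, TF-IDF vs a two-pass hand computation.

## Known limitations

* The intersection heuristic has no formal error control (no stability
  selection or knockoffs); it is an empirical filter for a handful of
  interpretable candidates.
* Dictionary-based entity matching finds only surface forms present in
  the configured term list.
* The union covariate set, time-dependent Cox models, competing risks and
  formal proportionality testing are out of scope; a Schoenfeld-style
  diagnostic is not run automatically.
* HR estimates on observational data remain associational; the package
  surfaces *candidate* confounders for clinical review, not causal
  certificates.
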