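# Methods

`readmit` implements a *data → prediction → action* pipeline for 30-day
all-cause hospital readmissions after a congestive-heart-failure (CHF)
admission: a risk classifier learned from binary-encoded visit data, the
manual LACE score as comparator, an expected-utility rule that allocates a
post-discharge intervention by a risk threshold, and a policy-value /
sensitivity analysis over intervention cost and efficacy. Because hospital
EHR extracts of this kind are not publicly deposited, the package ships a
seeded synthetic-cohort generator that reproduces the statistical structure
the analysis assumes; every stage is tested against cohorts with known
ground truth.

## The decision model

For a patient with 30-day readmission probability *p*, doing nothing costs
*pC* in expectation, where *C* is the expected cost of one readmission.
Applying an intervention with per-patient cost *c* and efficacy *α* (the
fractional reduction in readmission probability) costs *c* + (1−α)*pC*.
The two lines cross at the threshold

&nbsp;&nbsp;&nbsp;&nbsp;*p\** = *c* / (*α C*),

and expected cost is minimized by intervening exactly on patients with
*p* > *p\**. Three simplifying assumptions are built in: *c*, *α* and *C*
are each the same for all patients a priori. Indifference at *p* = *p\**
is broken toward **not** intervening — at the crossing point the two
expected costs are equal, and we prefer not to spend under indifference.
*C* defaults to the empirical mean readmission cost among readmitted
derivation-cohort visits; it can be overridden to fold non-monetary
penalties into the "cost" of a readmission.

Policies are scored two ways:

* **observed** — against realized outcomes *y<sub>i</sub>* and per-visit
  readmission costs: savings% = 100·[α·Σ<sub>treated</sub> y<sub>i</sub>cost<sub>i</sub> −
  c·n<sub>treated</sub>]/T with T = Σ y<sub>i</sub>cost<sub>i</sub>; readmissions
  prevented% = 100·α·Σ<sub>treated</sub> y<sub>i</sub>/Σ y<sub>i</sub>. For the
  apply-to-all policy this reduces exactly to 100·(α − cN/T).
* **expected** — y<sub>i</sub>cost<sub>i</sub> ↦ p<sub>i</sub>C and
  y<sub>i</sub> ↦ p<sub>i</sub> under a probability model. When the model used
  for evaluation is the same one used for allocation, the threshold policy
  is the exact expected-cost optimizer, so its savings dominate every other
  allocation — a property the tests verify by exhaustive enumeration on
  small cohorts.

Whether a published policy table of this kind was computed in observed or
expected mode is not always determinable; both are implemented and the
pipeline writes both tables side by side.

The sensitivity sweep recomputes *p\**, re-allocates and re-scores for every
cell of a cost × efficacy grid (default 50×50 over $0–$2,500 and α
0.05–0.60, covering the intervention costs and efficacies reported in the
readmission-program literature) and reports three savings surfaces:
patient-specific vs no action, vs the best uniform policy (treat all or
none, whichever is better), and vs a LACE-guided threshold policy. Two
boundary regimes are structural: as *c* → 0 everyone is treated under
either policy, and for *c* large no one is, so the gain over best-uniform
vanishes at both cost extremes and peaks in between.

## Risk models

**Classifier.** Visits are encoded as sparse binary vectors (lab
reference-range bins, low within-visit lab variation, utilization
("engagement") threshold rules, ICD-9 prefix history, medication on/off,
demographic categories; column order is sorted and deterministic, and
nothing derived from the outcome or its cost enters the matrix). The
classifier minimizes (1/n)·Σ log-loss + λ‖β‖₁ with an unpenalized
intercept (scikit-learn saga solver, plus an exact one-dimensional Newton
polish of the intercept, which saga moves slowly under strong penalty).
λ is selected from a log-spaced grid by mean out-of-fold AUC under seeded,
outcome-stratified k-fold cross-validation (default k=10); ties break
toward the sparser model, and an optional one-standard-error rule picks the
sparsest λ whose CV AUC is within one SE of the best — the configuration
used in the sparse-recovery tests, because the CV-AUC-optimal λ
deliberately overselects.

**Calibration.** Raw predictions are recalibrated by Platt scaling
(logistic regression of the outcome on the logit score) fitted on
*out-of-fold* derivation predictions — in-sample predictions of a model
this flexible are optimistic and would bias the recalibration. Calibration
is reported per risk group: tertile cutpoints of the derivation
predictions, reused on validation, with each group's observed rate,
predicted mean and binomial SE.

**LACE.** The comparator sums points for Length of stay (0–7), Acuity of
admission (3 if emergent), Charlson comorbidity index (0–5, computed from
ICD-9 history with a shipped Deyo-style prefix map, configurable) and
ED visits in the prior 6 months (capped at 4); totals range 0–19. The
integer score is mapped to a probability by univariate logistic regression
on the derivation cohort. Risk-group reclassification between LACE and the
classifier is reported as a row-normalized 3×3 percentage matrix.

## Synthetic cohorts

The generator emulates the study conditions: 1,172 visits split 793/379
into derivation/validation by admit-date windows (Jul 2007–Jun 2009 and
Aug 2009–Jun 2010), ~3,388 sparse binary features of which ~253 carry
signal, 25% readmission prevalence, and right-skewed readmission costs with
mean $13,679.

* **Features** are i.i.d. Bernoulli(density) by default (default density
  0.02 — sparse, EHR-like indicators); an equicorrelated-block option
  (Gaussian copula) exists because real EHR binaries are correlated.
  Latent features surface as synthetic diagnosis codes (`SYN0000`, …), so
  the ordinary encoding path reconstructs the design matrix exactly and
  end-to-end recovery is a real test of the pipeline, not a shortcut.
* **Outcomes** are Bernoulli(p) with logit p = β₀ + xᵀβ; the active
  coefficients are Normal(0, coef_scale²) and β₀ is tuned by bisection to
  hit the target prevalence within ±0.005 (an unreachable target raises a
  tuning error). Default coef_scale 0.35 puts the ground-truth AUC near
  0.7, the discrimination range reported for readmission models. Each
  record keeps its true probability for oracle comparisons.
* **Costs** for readmitted visits are lognormal, moment-matched to the
  target mean and SD (m = ln(μ²/√(μ²+σ²)), s² = ln(1+σ²/μ²)); lognormal is
  a package choice for the right skew — the study reports only mean
  ($13,679) and SE ($1,214). Default SD $12,000 (heavy right tail, CV ≈ 0.9,
  typical of hospitalization costs).
* **LACE ingredients** (length of stay, emergent admission, Charlson codes,
  prior utilization) are coupled to the true linear predictor only weakly
  (`lace_signal`, default 0.3), so the manual score is informative but
  systematically worse than the learned classifier — the regime the
  comparison studies.
* **Exclusion flags** for the five CMS-style rules (non-FFS enrollment,
  in-hospital death, left against medical advice, acute-facility transfer,
  index-admission/readmission conflict) are drawn independently at
  configurable rates; the default is 0 because the emulated 1,172-visit
  cohort is already post-exclusion. Excluded-visit counts attribute each
  visit to the first triggering rule in the canonical order.
* **Outside-hospital readmissions** are flagged at window-specific
  fractions (defaults 35.2% derivation / 47.9% validation); an optional
  label-hiding mode observes them as non-events to mimic the real
  difficulty of readmissions to other facilities (off by default).

What the generator does **not** emulate: realistic ICD-9 epidemiology,
longitudinal disease trajectories, patient-level repeat visits (each
synthetic visit has its own patient; the 30-day outcome-definition
operation is exercised on constructed visit histories in tests),
nonstationarity between derivation and validation windows, and
feature–outcome confounding beyond the planted linear model. Passing tests
therefore demonstrate that the machinery is correct and recovers planted
structure at realistic sizes — not that any particular hospital's accuracy
would be attained.

## Numerical choices and conventions

* 30-day window is half-open on the left and closed on the right: a
  readmission exactly 30 days after discharge counts; the discharge day
  itself does not. Overlapping stays for one patient raise a data error.
* ICD-9 matching is string-prefix on normalized codes (dots stripped,
  trailing `x` wildcards dropped).
* Lab bins come from the recorded low/normal/high flag (`elevated` aliases
  `high`), so exactly one bin column is set per lab present; the shipped
  reference ranges are standard adult values and fully configurable.
* "Absence" indicators (not on a medication, ER visits < 2) legitimately
  fire on visits with no recorded data; presence-type columns stay zero.
* Degenerate tertiles (near-constant predictions) raise a configuration
  error rather than silently merging groups; explicit cutpoints can be
  passed instead. Empty groups under user cutpoints are an error.
* λ→∞ collapses the classifier to intercept = logit(prevalence); λ = 0 is
  fitted unpenalized (lbfgs, tol 1e-10) and matches a Newton/IRLS oracle to
  1e-4 in tests.
* A negative calibrated LACE slope (anti-predictive score) warns but keeps
  the fit.
* Problem sizes used by the test suite: the recovery study uses n = 4,000
  visits, 200 features, 20 active (coefficient scale 0.8, density 0.1,
  seed 7) — large enough that the fitted AUC sits within 0.05 of the
  ground-truth ceiling while the whole suite stays fast; enumeration
  checks use cohorts of ≤ 12 visits against all 2ⁿ allocations; the demo
  pipeline runs 1,200 visits × 300 features in under a minute.

## Known limitations

* The expected-mode dominance of the threshold policy holds with respect to
  the probability model used for evaluation; under the simulator's ground
  truth the fitted classifier is near- but not exactly optimal.
* Published coefficient tables of this kind are sometimes rescaled or
  fold-averaged; the coefficient report here is explicitly the penalized
  log-odds coefficients of the final fit, with cross-validation SEs
  reported at the model level.
* No bootstrap confidence intervals on savings; no patient-specific
  efficacy or cost heterogeneity (excluded by the model's assumptions); no
  Medicare penalty structure.
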