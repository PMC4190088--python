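# readmit

Risk prediction and intervention allocation for 30-day hospital
readmissions after congestive-heart-failure (CHF) admissions.

Hospitals face a recurring operational question: a post-discharge program
(follow-up calls, early outpatient visits, home visits) costs *c* dollars
per enrolled patient and reduces a patient's 30-day readmission
probability by a fraction *α* — **who should get it?** `readmit`
implements the full *data → prediction → action* pipeline for answering
that question from visit-level EHR-style data:

1. **Cohort preparation** — CMS-style eligibility rules (fee-for-service
   enrollment, in-hospital death, left against medical advice, transfer,
   index/readmission conflict), the 30-day all-cause readmission outcome,
   date-window derivation/validation splits, and encoding of each visit
   into sparse binary indicators (lab reference-range bins, lab-variation
   flags, utilization rules, ICD-9 prefix history, medications,
   demographics).
2. **Risk models** — an L1-penalized (LASSO) logistic classifier with
   cross-validated λ selection by out-of-fold AUC, Platt recalibration,
   tertile calibration reports, and the manual LACE score
   (Length of stay / Acuity / Charlson / ED visits, 0–19 points) as a
   comparator, with a 3×3 reclassification matrix between the two.
3. **Decision analysis** — the expected-utility threshold
   *p\** = *c*/(*αC*): not intervening costs *pC* in expectation,
   intervening costs *c* + (1−α)*pC*, and total expected cost is minimized
   by treating exactly the patients with *p* > *p\**.
4. **Policy evaluation** — savings (% of total readmission costs) and
   readmissions prevented (%) for patient-specific, apply-to-all,
   apply-to-none and LACE-guided policies, plus cost × efficacy
   sensitivity sweeps producing contour-map surfaces.
5. **Synthetic cohorts** — a seeded generator with planted ground truth
   (sparse logistic signal, tuned prevalence, moment-matched lognormal
   readmission costs, weakly-informative LACE ingredients), since real
   hospital extracts of this kind are not public.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Run the demo pipeline (synthetic cohort of 1,200 visits, ~1 minute):

```bash
readmit -v run-all --config configs/demo.yaml --out-dir runs/demo
```

The manifest it prints (abridged) shows what happened at each stage:

```
prep: 1053 eligible → 715/338        # five CMS rules removed 147 visits,
                                     # date windows split the remainder
fit: λ=0.00562, 16 features selected # LASSO kept 16 of 353 binary columns
score: validation AUC classifier=0.629 LACE=0.583
decide: p*=0.2502, 97/338 treated    # c=$1300, α=0.35, C=$14,842 (empirical)
```

The classifier discriminates better than LACE (AUC 0.629 vs 0.583), and at
these program parameters the threshold p\* = 1300/(0.35·14842) ≈ 0.25
selects 97 of 338 validation visits for the intervention.
`runs/demo/policy_comparison_observed.csv` compares policies on the
validation cohort's actual outcomes and costs — for example (values
printed by the run above, in %):

| cost | efficacy | classifier | LACE | all | best uniform |
|------|----------|-----------|------|-----|--------------|
| $300  | 0.35 | 26.4 | 26.4 | 26.4 | 26.4 |
| $800  | 0.35 | 14.0 | 12.4 | 12.2 | 12.2 |
| $1300 | 0.35 |  3.1 |  2.2 | −2.1 |  0.0 |
| $1800 | 0.35 | −0.3 |  0.3 | −16.3 | 0.0 |

Reading it: when the program is cheap, treating everyone is optimal and
patient-specific targeting adds nothing; at intermediate cost the targeted
policy saves 3.1% of total readmission costs while blanket enrollment
*loses* 2.1%; when the program is too expensive, doing nothing is best.
The better score extracts more value than LACE precisely in that
intermediate band — `runs/demo/sensitivity.csv` maps the full surfaces.

Every stage is also available as its own subcommand (`simulate`, `prep`,
`fit`, `score`, `decide`, `evaluate`, `sweep`, `report`) for partial reruns
on saved intermediate files; the library functions under `readmit.*` expose
the same operations to Python.

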