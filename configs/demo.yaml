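# Demonstration run: a small synthetic cohort, full pipeline.
seed: 42
simulate:
  n_visits: 1200
  n_features: 300
  n_active_features: 30
  feature_density: 0.1
  coef_scale: 0.5
  base_rate: 0.25
  cost_mean: 13679.0
  cost_sd: 12000.0
  exclusion_rates:
    non_FFS: 0.05
    died_in_hospital: 0.02
    left_AMA: 0.01
    transferred_acute: 0.02
    is_readmission_of_index: 0.03
fit:
  k_folds: 5
  one_se_rule: false
decision:
  intervention_cost: 1300.0
  efficacy: 0.35
  readmission_cost: null   # null -> empirical mean readmission cost (derivation)
evaluate:
  mode: observed
  cost_values: [300.0, 800.0, 1300.0, 1800.0]
  efficacy_values: [0.25, 0.35]
sweep:
  cost_axis: {start: 0.0, stop: 2500.0, num: 12}
  efficacy_axis: {start: 0.05, stop: 0.60, num: 12}
  mode: expected
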