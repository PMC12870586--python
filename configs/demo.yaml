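# Desk-scale demonstration cohort: ~800 individuals, 60 signals, 5 outcomes,
# four planted protein->outcome effects, one APOE-shifted signal and one
# protective dementia signal.
seed: 1

cohort:
  n_families: 360
  family_size_weights: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.07, 5: 0.03}
  relatedness_within: 0.5

proteome:
  n_signals: 60
  n_factors: 8
  genetic_variance_fraction: 0.3
  noise_sd: 0.6

effects:
  n_outcomes: 5
  residual_outcome_correlation: 0.4
  true_effects:
    - [3, 0, 0.35]
    - [3, 2, 0.30]
    - [17, 1, -0.35]
    - [42, 4, 0.35]

covariates:
  missingness: {alcohol: 0.09, simd: 0.06, smoking_score: 0.03, education: 0.05,
                depression: 0.02, diabetes: 0.02, high_blood_pressure: 0.02, bmi: 0.01}

apoe:
  frequency: 0.15
  shifts: {signal_010: -0.1}

survival:
  baseline_hazard_scale: 105
  shape: 4
  log_hr: {20: -0.288}
  entry_age_range: [40, 80]
  censor_age_cap: 100
  admin_censor_fraction: 0.0
  max_follow_up: 17
  frailty_variance: 0.25

preprocess:
  k: 5
  min_measured_fraction: 0.4

joint:
  n_iter: 5000
  burn_in: 1000
  chains: 2
  pip_threshold: 0.95
  ci_level: 0.95

analysis:
  alpha: 0.05
  variance_target: 0.80
  min_age: 65
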