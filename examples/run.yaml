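# Full-pipeline configuration (sig run --config run.yaml).
seed: 1
representation: signature        # which representation's confusion matrices to render
n_train_per_group: 21
n_test:
  stable_NL: 20
  converter: 10
  stable_MCI: 6
folds: 10
n_lambdas: 100
lambda_min_ratio: 0.001
age_tolerance: 5.0
train_window: [0, 24]
train_min_points: 4
test_window: [12, 36]
test_min_points: 3
train_conversion_month: 36
train_stability_months: 72
test_conversion_month: 48
test_stability_months: 84
effect_factor: 1.0
null_effects: false
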