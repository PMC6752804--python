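# Synthetic cohort generator parameters (sig simulate --config params.yaml).
# Every key below shows its default; omit any key to keep the default.

# subjects per diagnostic group
n_per_group:
  stable_NL: 21
  converter: 21
  stable_MCI: 21

# baseline volume medians on the scaled analysis scale
# (whole brain / 1e6 mm^3, hippocampus and ventricles / 1e3 mm^3)
baseline_location:
  stable_NL: [1.02, 7.21, 28.53]
  converter: [1.00, 6.14, 34.34]
  stable_MCI: [1.00, 7.10, 33.88]
baseline_spread:
  stable_NL: [0.096, 0.91, 13.8]
  converter: [0.089, 1.05, 15.7]
  stable_MCI: [0.089, 0.66, 19.9]

# base linear trends, scaled units per month (whole brain, hippocampus,
# ventricles); stable groups decline steadily, converters start flat on the
# hippocampus and pick up the planted acceleration below
atrophy_rate:
  stable_NL: [-0.002, -0.0229, 0.125]
  converter: [-0.002, 0.0, 0.125]
  stable_MCI: [-0.002, -0.0229, 0.130]

# extra converter decline switched on at
# conversion_month - accel_onset_before_conversion
ad_acceleration:
  hippocampus: 0.0375
accel_onset_before_conversion:
  hippocampus: 24.0

# amplitude of the converters' zero-net whole-brain transient (above trend
# early in the pre-conversion window, below trend late)
wb_transient: 0.05

visit_months: [0, 3, 6, 12, 18, 24, 36, 48]
visit_missing_prob:
  3: 0.6
  6: 0.05
  12: 0.05
  18: 0.1
  48: 0.1
never_missing_months: [0, 24, 36]

measurement_noise_sd: [0.006, 0.045, 1.2]
rate_jitter: 0.15

age_range: [60, 90]
conversion_month: 36
stability_months: 72
dx_interval: 6
converter_pre_mci_prob: 0.9047619047619048
male_prob: 0.5
id_prefix: TR
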