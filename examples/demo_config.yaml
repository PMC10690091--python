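# Demo configuration for `serdstudy report --config examples/demo_config.yaml`
# (these values mirror the built-in defaults; edit freely).
study:
  doses_mg_per_kg: [1.0, 3.0, 10.0, 30.0]
  n_per_arm: 8
  duration_days: 28.0
  molecular_weight: 450.0
noise:
  volume_cv: 0.15
  conc_cv: 0.15
  er_cv: 0.15
cohort:
  n_models: 10
  sensitive_fraction: 0.6
  n_per_arm: 4
  duration_days: 21.0
alpha: 0.05
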