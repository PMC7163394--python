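# Example run configuration for `capribite all --config examples/config.yaml`.
# Omitted keys keep the reference-protocol defaults (2-min sampling, 22-h
# window, 5-g resolution, 8 slope clusters, 30-min pause, 0.95 threshold).
seed: 7
design:
  n_goats: 12
  n_alpine: 5
  n_periods: 3
  n_days_per_period: 4
variances:
  sd_noise: 2.0
  bump_prob: 0.002
min_pause: 30.0
repeatability_threshold: 0.95
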