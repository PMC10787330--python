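# Example configuration for the synthetic demo pipeline:
#   workmode --config examples/run.yaml demo
seed: 1
paths:
  outdir: workmode_out
simulate:
  n_participants: 5
  n_days: 20
  contrast: 1.0
  holiday_prob: 0.2857
  gps_noise_sd_km: 0.05
holdout_fraction: 0.3
pipeline:
  geofence_radius_km: 1.0
  confirm_s: 1800
  window_s: 1800
  prob_threshold: 0.5
  transition_exclusion_min: 15
stage1:
  max_depth: 4
  learning_rate: 0.1
  n_estimators: 400
cnn:
  lookback: 30
  filters: [32, 64, 64]
  kernels: [5, 5, 3]
  epochs: 60
  patience: 5
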