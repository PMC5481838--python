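# Full-pipeline demo config: simulate a homogeneous Brownian ensemble, filter,
# fit MSDs, scan CER threshold sets and classify mechanisms.
# Run with: subdiff run --config examples/pipeline.yaml --out results/demo
# A single-state ensemble is a negative control for segmentation: the
# guideline filter is expected to accept no three-state threshold set.
seed: 1
simulate:
  n_particles: 200
  n_steps: 400
  process: brownian
  step_scale: 30.0        # nm-scale steps
  noise_sigma: 0.0
filter:
  enabled: true
  threshold: 2.11
msd:
  max_lag: 100
  fit_range_e: [1, 50]
  fit_range_t: [10, 30]
segment:
  threshold_sets:
    - {R_th: [60.0, 150.0], n_th: [10, 5]}
    - {R_th: [80.0, 150.0], n_th: [10, 5]}
mechanisms:
  enabled: true
  deltas: [1, 2, 4, 8, 16, 32]
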