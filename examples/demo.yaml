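# Small end-to-end demonstration scenario.
seed: 1
scenario:
  n_units: 20
  n_clusters: 4
  n_periods: 60
  n_covariates: 2
clustering:
  n_clusters: 4
  mode: knn
  k: 4
graph:
  gamma: 0.5
  q: 0.75
model:
  name: M1
inference:
  grid_size: 8
evaluation:
  origin: 54
  horizon: 6
  mode: simultaneous
  n_draws: 2000
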