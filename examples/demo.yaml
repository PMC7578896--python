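# Desk-scale demo pipeline (~15 min on one CPU).
# Omitted fields fall back to the package defaults; run e.g.
#   chromoswitch synth --config examples/demo.yaml --seed 1 --outdir demo_run
synthetic:
  n_bins: 100
  exponents: [-1.5, -1.0]
  switch_fraction: 0.3
  plaid_strength: 0.3
  tad_strength: 1.0
  mean_block_bins: 15
  mean_tad_bins: 9
maxent:
  schedule: [[20, 1000, 8.0], [10, 2000, 3.0]]
  n_replicas: 12
  production_taus: 12
switching:
  n_sample: 120
  min_population: 0.01
  max_trajectories: 12
  t_min: 0.1
  t_max: 50.0
  per_decade: 8
  pre_switch_taus: 5.0
analysis:
  n_stages: 4
  compartment_coarsen: 5
  insulation_window: 5
  ps_fit_range: [4, 40]
  kmeans_k: 2
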