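# demo pipeline config: small synthetic world, reduced MCMC profile
seed: 7
world:
  n_mice: 20
  grid_side: 12
  n_loggers: 40
  n_nights: 60
  n_asv: 120
  n_genera: 12
  samples_per_mouse: 2
  detection_rate: 8.0
bandwidth: 15.0
min_detections: 10
metric: jaccard
mcmc:
  chains: 2
  warmup: 300
  draws: 700
run_importance: false
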