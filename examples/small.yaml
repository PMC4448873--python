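# Desk-scale end-to-end run: ~100 birds on a 3x3 feeder grid over 4
# two-day sampling periods, with a planted mixed-sex grouping preference.
out_dir: flocknet_run
seed: 42
simulation:
  n_individuals: 100
  n_feeders: 9
  n_periods: 4
  social_preference:
    same_sex: 0.25
node_iterations: 200
stream_iterations: 10000
sample_every: 100
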