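# Demo configuration for `morphodyn all`: simulate a 32-tip world with a
# planted 8x clade shift, then run the full analysis at desk scale.
out_dir: morphodyn_out
seed: 42
simulate:
  n_tips: 32
  shift_scalar: 8.0
dating_method: mbl
min_branch: 1.0
n_trees: 20
metrics: [mpd, mst]
n_boot: 500
n_bins: 12
n_slices: 12
rates_trees: 3
chain:
  iterations: 50000
  burn_in: 10000
  thinning: 100
  n_stones: 10
  stone_iterations: 1000
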