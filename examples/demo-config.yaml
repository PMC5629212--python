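# Demo pipeline configuration: small enough to finish in ~10 s.
#   cytocausal run-all --config examples/demo-config.yaml
out_dir: demo-run
seed: 5
p: 3
edge_density: 0.6
n_inhibitors: 12
n_dosages: 4
n_per_condition: 150
min_support: 4
n_sim: 20
min_success: 10
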