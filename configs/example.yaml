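# Example configuration for `uprnet all --config configs/example.yaml`.
# Every published default is a named key; nothing is hard-coded.
organisms:
  - Drosophila melanogaster
  - Arabidopsis thaliana
  - Caenorhabditis elegans
score_threshold: 0.400   # STRING medium confidence, inclusive
ensemble_size: 10        # configuration-model replicates R
attack_strategies: [random, degree, closeness, betweenness]
attack_direction: ascending
attack_efficiency: true  # all-pairs efficiency traces (quadratic per step)
jump_threshold: 0.10     # LCC collapse of at least 10% of N
enumerate_drivers: true
driver_set_cap: 64
seed: 0
outdir: results/pipeline
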