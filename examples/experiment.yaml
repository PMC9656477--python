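# Reduced-scale release experiment on the reference nanogel:
# 1.75-nm drug loaded throughout a flexible gel, 3 series of 3 replicates.
n_chains: 692
chain_length: 4
n_crosslinkers: 404
mode: flexible
t_end: 20.0          # ns
n_drug: 100
solute_diameter: 1.75
loading: throughout
n_replicates: 3
n_series: 3
base_seed: 7
output_dir: results/throughout_flexible
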