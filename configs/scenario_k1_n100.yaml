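# Simulation scenario preset: noise scaling k=1, 100 causal SNPs.
# Genotype/model sizes are desk-scale defaults; at full scale set
# n_positions to the array panel size and model_preset to genome-wide.
k: 1.0
n_causal: 100
case_fraction: 0.1985
n_individuals: 2000
n_positions: 5000
m: 5
m_null: 5
theta: strict
attribution_method: IG
n_reps: 100
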