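# Example simulation config for `kinsig simulate --config examples/sim.yaml`
population_size: 500
sample_size: 31
gene_length_bp: 600
per_site_mutation_rate: 1.0e-5
selection_coefficient: 0.02
true_relatedness: 0.5
num_genes_per_class:
  cooperative: 25
  private: 50
  background: 50
outgroup_expected_Ks: 0.3
missingness_rate: 0.05
seed: 11
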