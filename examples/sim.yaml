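# Full-pipeline run on a simulated experiment (all thresholds at defaults).
seed: 1
simulation:
  n_genes: 500
  events_per_gene: 1.2
  n_replicates: 3
  fraction_regulated_splicing: 0.10
  delta_psi: 0.3
  fraction_regulated_expression: 0.05
  expr_log2fc: 1.0
thresholds:
  expressed: 500
  fc_min: 1.5
  alpha_gene: 0.05
  alpha_probeset: 0.01
  scale_target: 500
  trim: 0.02
  r_min: 0.7
  min_keep: 3
  probe_test_on: si
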