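# Default end-to-end run: fully simulated study with planted ground truth.
seed: 0
output_dir: lncarray_results
de_regime: primary
thresholds:
  fc_min: 2.0
  p_max: 0.05
  fdr_max: 0.05
  bidirectional_window: 1000
  neighbor_window: 300000
simulation:
  n_coding: 1500
  n_lncrna: 500
  n_samples_per_group: 4
  planted_de_fraction: 0.05
  planted_log2fc: 2.0
  noise_sd: 0.25
  baseline_log2_mean: 8.0
  n_lincrna_pairs: 40
  concordant_fraction: 0.685
enrichment:
  n_sets: 20
qpcr:
  n_replicates: 4
  noise_sd: 0.25
  n_genes: 9
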