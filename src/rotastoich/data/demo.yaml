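# Demo pipeline configuration: synthetic data at the bundled rotation-study
# generating parameters (4 treatments x 3 replicate plots), one bacterial-like
# and one fungal-like count matrix, all stages enabled.
seed: 42
treatments: [B1, B2, B3, B4]
n_replicates: 3
alpha: 0.05
soil:
  bundled_params: true
  include_micronutrients: true
# Abundance gradients (log_mean_range) give each community a realistic
# long tail of rare taxa, so richness estimates vary across samples.
counts:
  bacterial:
    n_taxa: 120
    read_depth: 60000
    n_samples_per_treatment: 10
    log_var: 1.0
    log_mean_range: [0.0, -14.0]
    corr_block: {taxa: [0, 1, 2, 3, 4, 5], rho: 0.95}
    fold_changes:
      B3: {6: 4.0, 7: 4.0, 8: 0.3}
      B4: {6: 4.0, 7: 4.0, 8: 0.3}
  fungal:
    n_taxa: 80
    read_depth: 60000
    n_samples_per_treatment: 10
    log_var: 1.5
    log_mean_range: [0.0, -14.0]
    corr_block: {taxa: [0, 1, 2, 3, 4, 5], rho: 0.95}
    fold_changes:
      B2: {6: 3.0}
      B3: {7: 0.2}
      B4: {7: 0.1}
community:
  permutations: 999
# Networks are inferred on the 15 most abundant taxa (coarse networks on
# the top taxa, as is common practice); 999 permutations so the
# BH-adjusted q can clear 0.01.
network:
  rho_min: 0.6
  q_max: 0.01
  permutations: 999
  top: 15
plspm:
  model: bundled
  scheme: path
  n_boot: 200
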