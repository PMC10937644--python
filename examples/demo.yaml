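# Demo study: synthetic multi-trait network-MR run at desk scale.
# All defaults are spelled out here for reference; `netmr pipeline` with no
# config uses the same values.
dag:
  n_snps_per_trait: 100
  maf_range: [0.05, 0.5]
  beta_exposure_sd: 0.05
  pleiotropy_mode: none
  pleiotropy_sd: 0.02
  ld_block_size: 5
  ld_rho: 0.3
  n_individuals: 30000
  seed: 0
sumstats_mode: direct
instruments:
  p_threshold: 5.0e-8
  clump_r2: 0.001
  clump_window_bp: 10000000
  f_min: 10.0
  palindrome_maf_max: 0.42
p_threshold_by_trait:
  fruit: 1.0e-5
  vegetables: 1.0e-5
n_boot: 1000
n_sim: 1000
include_exposure_in_mvmr: true
mediation_b_source: mvmr
outdir: netmr_output
seed: 0
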