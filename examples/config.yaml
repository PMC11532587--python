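# Reference pipeline configuration (all keys optional; defaults shown).
# Run with:  smokemr --config examples/config.yaml --outdir out all
simulation:
  n_individuals: 20000        # analysis cohort size
  gwas_n_individuals: 50000   # each summary-statistics cohort
  n_snps: 42
  maf_range: [0.10, 0.50]
  instrument_effects: 0.1     # index units per effect allele
  causal_effect: 0.0          # log-odds of CKD per index unit (null)
  confounder_effects: [0.4, 0.5]   # on exposure (index/SD), on log-hazard (/SD)
  pleiotropy: [0.0, 0.0, 0.0]      # fraction of SNPs, mean, sd (log-odds/allele)
  admin_censor_days: 4675
  never_smoker_fraction: 0.549
  seed: 0

analysis:
  p_threshold: 5.0e-8         # genome-wide instrument selection
  n_measured_snps: 14         # directly-genotyped restriction (one-sample arm)
  n_boot: 500                 # bootstrap resamples for one-sample CIs
  lace_strata: 3
  bmi_cut: 25.0
  min_followup_days: 180.0
  palindromic_eaf_window: [0.42, 0.58]
  spline_df: [2, 3, 4]
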