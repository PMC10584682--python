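# Default shipped configuration: synthetic-data conditions plus analysis
# tunables.  Any omitted key keeps its library default.
synthetic:
  seed: 0
  n_genes: 600
  n_chroms: 4
  identity_fraction: 0.25
  planted_fraction: 0.5
  breadth_reduction_factor: 0.5
  body_bias: 1.0
  expression_reduction_log2fc: -1.0
  n_replicates_per_condition: 3
  nb_dispersion: 60.0
  coverage_depth: 10.0
analysis:
  promoter_upstream: 2000
  quartile_low: 0.25
  quartile_high: 0.75
  de_alpha: 0.05
  flank_bp: 2000
  flank_bin_bp: 50
  n_body_bins: 100
io:
  outdir: broaddomain_run
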