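# Demo pipeline configuration: the study conditions this package models.
seed: 0
out_dir: bulkmap_demo

sim:
  n_chromosomes: 11
  chrom_length_bp: 30000000
  chrom_length_cM: 100.0
  n_variants_per_chrom: 4000
  n_f2: 241
  bulk_size: 30
  mean_depth: 53.83
  seq_error_rate: 0.01
  causal_chrom: 5          # 0-based -> chr6
  causal_pos_bp: 23800000
  dominance: true
  gq_fail_fraction: 0.02

bsa:
  gq_min: 50
  window_bp: 200000
  step_bp: 100000
  threshold_mode: quantile
  n_sims: 2000
  level: 99

finemap:
  region_start_bp: 23450000
  region_end_bp: 24220000
  n_markers: 21
  n_f3: 847
  flank_left: ST9
  flank_right: ST12

panel:
  n_green: 26
  n_yellow: 19
  discordant: 0
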