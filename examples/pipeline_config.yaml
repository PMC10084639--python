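# Desk-scale experiment config: simulate -> QC -> GRM -> h2 -> stGWAS ->
# mtGWAS / metaGWAS (complete-case and all-available) -> QTL -> comparison.
seed: 11

simulation:
  n_samples: 1000
  n_variants: 4000
  chrom_lengths: {'1': 5000000, '2': 5000000, '3': 5000000, '4': 5000000}
  trait_groups:
    production: [ADFI, DWG, BFT]
  h2: {ADFI: 0.37, DWG: 0.24, BFT: 0.47}
  genetic_corr:
    - [1.0, 0.5, 0.3]
    - [0.5, 1.0, 0.2]
    - [0.3, 0.2, 1.0]
  qtl:
    - {chrom: '1', pos: 2500000, fractions: {ADFI: 0.04, DWG: 0.03}}
  missing_rate: 0.15
  reliability_range: [0.4, 0.95]

drebv_filters:
  min_reliability: 0.3
  sd_limit: 5.0
  min_records: 200

qc:
  maf_min: 0.05
  hwe_p_min: 1.0e-5
  var_call_min: 0.8
  sample_call_min: 0.8

scan:
  alpha: 0.05
  maf_min: 0.05
  df_mode: d_minus_1      # the statistic can also be referred to d df
  v_mode: all_markers
  merge_adjacent: true

conditional_finemap: true
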