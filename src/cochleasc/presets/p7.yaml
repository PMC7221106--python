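# P7 cochlear-duct floor emulation: 12 cell-type expression programs.
generator:
  n_genes: 2000
  n_types: 12
  n_cells_per_type: 100
  markers_per_type: 25
  marker_fold: 6.0
  qc_outlier_fractions:
    low_complexity: 0.02
    high_complexity: 0.01
    high_mito: 0.01
    high_stress: 0.01
pipeline: {}
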