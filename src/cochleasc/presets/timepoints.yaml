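# Two-timepoint pathway-shift emulation (earlier vs later stage).
generator:
  n_genes: 2000
  n_types: 3
  n_cells_per_type: 150
  markers_per_type: 25
  marker_fold: 6.0
  pathways:
    names: [glycolysis, tca, oxphos, ppp, fao, aa_metab]
    genes_per_pathway: 20
    up_frac: [0.8, 0.1, 0.7, 0.2, 0.75, 0.15]
    down_frac: [0.1, 0.8, 0.2, 0.7, 0.15, 0.75]
    shift_logfc: 0.6931471805599453
pipeline: {}
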