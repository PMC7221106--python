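# TF-driven co-expression programs: one active cell type per regulon.
generator:
  n_genes: 2000
  n_types: 5
  n_cells_per_type: 150
  markers_per_type: 25
  marker_fold: 6.0
  regulons:
    n_tfs: 5
    targets_per_tf: 20
    coupling_strength: 0.8
pipeline: {}
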