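# Outer-hair-cell differentiation continuum: four temporal gene modules
# (early-decreasing, transient-peak, mid-rising, late-rising).
generator:
  n_genes: 2000
  n_types: 1
  n_cells_per_type: 600
  markers_per_type: 1
  marker_fold: 6.0
  trajectory:
    n_cells: 600
    n_modules: 4
    genes_per_module: 50
    templates: [early_decreasing, transient_peak, mid_rising, late_rising]
pipeline:
  trajectory:
    n_modules: auto
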