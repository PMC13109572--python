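# Small demonstration stand: 10 trees, coarse rasters, light CV.
# Runs the full simulate -> stats pipeline in well under a minute.
stand:
  n_rows: 2
  n_cols: 5
  n_families: 5
simulate:
  point_density: 25.0
model:
  cv_folds: 5
  cv_repeats: 1
  importance_repeats: 3
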