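# Example run configuration for `deapanel run-all --config examples/run_config.yaml`.
# Scaled-down conditions; raise n_jurisdictions/B for full-size runs.
seed: 1
outdir: deapanel_output
synthetic:
  n_jurisdictions: 60
  years: [2009, 2020]
bootstrap:
  B: 100
  ci_level: 0.95
determinants:
  n_trees: 500
  vars_per_split: 5
  cv_folds: 10
  cv_repeats: 3
  n_importance_subsamples: 50
  n_pd_observations: 500
summary:
  anchor_years: [2009, 2015, 2020]
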