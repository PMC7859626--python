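# Demo pipeline config: small synthetic cohort with one planted signal
# pathway, analyzed with the pathway-eigengene PRD classifier.
recipe: prd_pathways
seed: 1
simulate:
  n_subjects: 60
  n_genes: 400
  n_pathways: 25
  genes_per_pathway: [6, 10]
  frac_signal_genes: 0.05
  signal_log2fc: 1.2
  signal_in_pathways: true
  signal_outcome: prd
  prd_missing_rate: 0.0
thresholds:
  fdr: 0.1
recipe_options:
  method: forward
  cv_folds: 5
  outer_folds: 5
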