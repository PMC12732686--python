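# Default pipeline settings: one metric per run, stratified 5-fold CV with
# the random state fixed at 0, both rank-weight schemes swept.
metric: AUC
positive_label: GBM
n_folds: 5
seed: 0

dialect:
  cell_line: CELL_LINE_NAME
  drug: DRUG_NAME
  tissue: TCGA_DESC

imputer:
  max_iter: 10
  tol: 1.0e-3
  estimator: bayesian-ridge
  seed: 0
  order: ascending-missingness

selector:
  lasso_path_size: 50
  lasso_inner_folds: 3
  lasso_coef_threshold: 1.0e-8
  mrmr_k: 30
  standardize: true
  seed: 0

evaluation:
  n_folds: 5
  n_trees: 100
  seed: 0
  pooling: pooled
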