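# Methods

## Endpoint and data model

The unit of analysis is a cell-line × drug matrix of one dose–response
summary metric (`LN_IC50`, `AUC`, `RMSE` or `Z_SCORE`), with a binary
endpoint per cell line: 1 if its tissue annotation matches the configured
positive label (default `GBM`, matched case-insensitively after trimming),
0 otherwise. The four metrics are analyzed separately; one pipeline run
handles one metric. A cell line carrying conflicting tissue annotations is
an error, never a majority vote — silent relabeling would corrupt the
endpoint. Rows and columns are kept lexicographically sorted everywhere, so
fold assignment, tallies and outputs are identical across runs.

Replicate measurements of a (cell line, drug) pair are combined with the
arithmetic mean at pivot time. Drugs with no observed value at all are kept
through the pivot and rejected loudly by the imputer; dropping them is the
caller's explicit decision, never an implicit side effect.

## Imputation

Missing cells are filled by round-robin iterative regression: initialize
with column means, then cycle over columns (default order: ascending
missingness), regressing each on all others over the rows where it is
observed and predicting its missing entries, until convergence or
`max_iter` (default 10) sweeps. The per-column model is Bayesian ridge
regression — after pivoting, the number of drugs can approach the number of
cell lines, so an unregularized fit is ill-posed. Imputed values are clipped
to each column's observed `[min − 3·SD, max + 3·SD]` to prevent divergence
on near-collinear columns (constant columns get a trivially widened window
so the bounds stay ordered). Convergence is declared when the maximum
absolute change of imputed entries, scaled by the largest observed
magnitude, drops below `tol` (default 1e-3). The implementation delegates
to scikit-learn's `IterativeImputer`; observed entries are additionally
restored bit-exactly after the fit.

Imputation runs once on the full matrix, before cross-validation. This is a
deliberate consistency choice and introduces a limited, documented leakage:
held-out rows influence the imputation model of training rows. Users who
want fold-clean imputation can call `iterative_impute` on each fold's rows
themselves; the function is pure and label-blind.

## Per-fold selectors

Stratified 5-fold CV with the random state fixed at 0 assigns folds; both
selectors see only each fold's training portion.

**LASSO.** Features are standardized to zero mean / unit variance
(population SD; zero-variance columns are left at zero and get zero
coefficients). An L1-penalized linear model of the 0/1 label is fitted over
50 log-spaced penalties, the penalty chosen by 3-fold inner stratified CV
minimizing squared loss, and the selection is every feature with
|coefficient| > 1e-8. The set is data-driven and may be empty. Columns are
sorted internally before the coordinate-descent fit, so the selection does
not depend on the caller's column order; standardization makes it invariant
to affine rescaling of any feature.

**mRMR (FCQ).** Relevance is the one-way ANOVA F statistic of a feature
grouped by the label; redundancy is the mean |Pearson correlation| with the
already-selected set, floored at 1e-6 so near-orthogonal features do not
produce unstable quotients. The first pick maximizes relevance; every later
pick maximizes relevance/redundancy. Exactly `k` features (default 30) are
returned in pick order, which makes the result at `k` a prefix of the
result at `k+1`. Zero-variance features have relevance 0 and correlation 0
by convention, so they are never picked before a feature with positive
relevance. Exact score ties resolve to the lexicographically smallest drug
name.

How many features each selector should contribute per fold is a genuinely
open design point; the defaults (data-driven set for LASSO, fixed `k = 30`
for mRMR) reflect each method's natural usage and produce union sizes in
the tens-to-low-hundreds on matrices of a few hundred drugs.

## Rank-weight tally, threshold sweep, final choice

A weight scheme assigns one selector weight 2 and the other weight 1; both
assignments are swept. Each feature accumulates, over folds, the weight of
every selector that picked it, so with 5 folds the cumulative weight lies
in `[1, 15]`: 15 means picked by both selectors in every fold, 1 means
picked once by the weight-1 selector. The candidate set at threshold `k` is
`{f : weight(f) ≥ k}` — a cumulative reading, under which candidate sets
nest, feature counts are non-increasing in `k`, and both schemes coincide
at `k = 1` (the union of all selections).

Each non-empty candidate set is scored by a fresh stratified 5-fold Random
Forest CV (100 trees, random state 0, no resampling of the class balance)
on the full matrix restricted to that set; confusion counts are pooled over
folds (a per-fold-mean mode exists behind the `pooling` flag), and accuracy
is also rendered as a percentage with three decimals. Because the score is
a pure function of the feature set, identical sets recurring across `k` and
across schemes are evaluated once and reused. Scoring candidate sets on the
same data that produced the selections shares the selection-then-evaluation
optimism of the full-matrix protocol; it is the protocol this package
implements, and the synthetic null control (below) quantifies its effect at
the chosen operating point. Empty candidate sets are recorded but excluded
from the final choice rather than scored as majority classifiers.

The final set maximizes accuracy; ties resolve to the minimum feature
count, then the larger threshold, then the LASSO=1/mRMR=2 scheme, then the
earlier sweep position — a fully deterministic rule.

## Attribution

The final forest (fitted on all rows, restricted to the chosen set) is
decomposed with tree-path additive attributions: walking each sample's
root-to-leaf path, the change in node value across every edge is credited
to the feature split at the parent, so per sample the credits plus the root
(base) value reconstruct the tree's output exactly, and averaging over
trees reconstructs the forest's positive-class probability exactly. This
additive path decomposition is deterministic and satisfies the local-
accuracy axiom by construction; it differs from Shapley-value attributions
in how credit is shared along correlated splits, which does not affect the
uses made of it here (ranking by mean |attribution| and a sign summary).
The sign summary is the Pearson correlation between a feature's values and
its attributions: positive means high feature values push the predicted
probability up.

## Synthetic data generator

The generator emulates the shape of a GDSC bulk download: long-format rows
(cell line, drug, tissue, four metric columns), ~3.4% positive cell lines,
per-drug MCAR missingness, and occasional replicate measurements. Drug
responses are drawn from a block-diagonal Gaussian (consecutive blocks of
`block_size` drugs with equicorrelation `block_rho`, default 0.5), which
gives mRMR's redundancy term real structure to penalize. Planted
informative drugs — placed one per block, so the planted signals are not
mutually redundant — receive an additive `effect_size` shift (default 2
latent SD) for positive cell lines on `LN_IC50` and `AUC` only; `RMSE` and
`Z_SCORE` are noise transforms with no class signal, mirroring their
semantics as a curve-fit-quality value and a normalization. One RNG stream
is consumed in a fixed order (labels → latents → missingness → replicates),
so identical specs give byte-identical datasets.

Defaults: 968 cell lines (the scale of one real screen), 120 drugs — a
deliberate scale-down from the ~300–400 compounds of the real screens that
preserves the p-vs-n regime while keeping a full sweep around a minute on
one CPU — missing rates uniform in (0.05, 0.40), replicate rate 0.05.

What the generator does *not* emulate: dose–response (Hill-curve)
pharmacology, assay covariates, non-Gaussian metric marginals, and
missingness that depends on the measured values (MNAR). Passing tests
therefore certify the machinery — recovery of planted signals under
imbalance, correlation and MCAR missingness — not performance on any real
screen, whose metric distributions are unknown to the generator.

## Numerical and degenerate-input conventions

- All randomness flows through explicit integer seeds; two runs with the
  same config and input are byte-identical (the manifest records a config
  hash and library versions).
- Accuracy identities: ACC = (TP+TN)/total = 1 − (FP+FN)/total; balanced
  accuracy needs both classes present and errors otherwise.
- Stratified folds require every class to have at least `n_folds` members;
  with 33 positives and 5 folds the per-fold positive counts are 6 or 7,
  negatives exactly proportional.
- A single-class label vector, an incomplete matrix reaching the selectors,
  `k` outside `[1, 15]`, or an unknown metric name all fail loudly with the
  offending field named.

## Known limitations

- Full-matrix imputation and same-data evaluation leak information, as
  discussed above; both are protocol-faithful choices, quantified on null
  data (where the chosen accuracy sits at the majority rate) rather than
  eliminated.
- The study-scale synthetic check uses 1000×120; behavior at much larger
  drug counts is extrapolated, not measured.
- The attribution backend is a path-dependent decomposition, not an exact
  Shapley value; rankings on strongly correlated chosen sets can differ
  from Shapley-based rankings.
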