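"""Rank-weighted accumulation of per-fold selections, threshold sweep, and
the max-accuracy / min-feature final selection rule.

This is the package's core procedure.  Within each of ``n_folds`` stratified
cross-validation folds, both base selectors (LASSO and mRMR) are run on the
fold's training portion.  Under a weight scheme assigning one selector
weight 2 and the other weight 1, every feature accumulates its selectors'
weights across folds, so with 5 folds a feature picked by both selectors in
every fold reaches the maximum cumulative weight 2x5 + 1x5 = 15, and a
feature picked once by the weight-1 selector scores the minimum, 1.  For
each scheme and each threshold k the candidate set is all features with
cumulative weight >= k — a cumulative reading, which makes feature counts
non-increasing in k and both schemes coincide at k = 1 (the union of all
selections).  Each non-empty candidate set is scored by stratified k-fold
Random Forest cross-validation, and the final set is the one maximizing
accuracy with, among ties, the minimum number of features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvalConfig, EvalResult, stratified_cv_accuracy, stratified_folds
from .exceptions import ValidationError
from .gdsc_io import ResponseMatrix
from .selectors import SelectorConfig, lasso_select, mrmr_select

LASSO = "LASSO"
MRMR = "mRMR"


@dataclass(frozen=True)
class WeightScheme:
    """Rank weights for the two selectors; exactly one of them gets 2."""

    w_lasso: int
    w_mrmr: int

    def __post_init__(self) -> None:
        if {self.w_lasso, self.w_mrmr} != {1, 2}:
            raise ValidationError(
                "weight scheme must assign {1, 2} across the two selectors"
            )

    @property
    def name(self) -> str:
        return f"LASSO={self.w_lasso},mRMR={self.w_mrmr}"


#: The two admissible schemes, in the preference order used for tie-breaks.
DEFAULT_SCHEMES = (WeightScheme(w_lasso=1, w_mrmr=2), WeightScheme(w_lasso=2, w_mrmr=1))


@dataclass
class FoldSelection:
    fold_index: int
    selector: str  # LASSO or mRMR
    selected: list[str]

    def __post_init__(self) -> None:
        if self.selector not in (LASSO, MRMR):
            raise ValidationError(f"unknown selector {self.selector!r}")
        if len(set(self.selected)) != len(self.selected):
            raise ValidationError("selected feature list contains duplicates")


@dataclass
class WeightTally:
    scheme: WeightScheme
    n_folds: int
    weights: dict[str, int]

    @property
    def max_possible(self) -> int:
        return (self.scheme.w_lasso + self.scheme.w_mrmr) * self.n_folds


@dataclass
class ThresholdResult:
    scheme: WeightScheme
    k: int
    features: frozenset[str]
    accuracy: float | None = None
    balanced_accuracy: float | None = None
    error: str | None = None

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class SweepResult:
    per_threshold: list[ThresholdResult]
    chosen: ThresholdResult
    selections: list[FoldSelection] = field(default_factory=list)


def run_fold_selections(
    matrix: ResponseMatrix,
    n_folds: int = 5,
    selector_config: SelectorConfig | None = None,
    seed: int = 0,
) -> list[FoldSelection]:
    """Run both selectors on each fold's training portion.

    Returns 2 x ``n_folds`` entries.  The matrix must be complete (imputed)
    and contain at least ``n_folds`` members of each class.
    """
    selector_config = selector_config or SelectorConfig()
    if not matrix.is_complete():
        raise ValidationError("matrix must be complete; run imputation first")
    matrix.require_both_classes()
    assignment = stratified_folds(matrix.labels, n_folds, seed)
    X = matrix.to_frame()
    y = matrix.labels

    selections: list[FoldSelection] = []
    for fold in range(n_folds):
        train = assignment != fold
        X_tr, y_tr = X.loc[train], y[train]
        lasso = sorted(lasso_select(X_tr, y_tr, selector_config))
        mrmr = mrmr_select(X_tr, y_tr, min(selector_config.mrmr_k, X.shape[1]))
        selections.append(FoldSelection(fold, LASSO, lasso))
        selections.append(FoldSelection(fold, MRMR, mrmr))
    return selections


def tally_weights(
    selections: list[FoldSelection], scheme: WeightScheme
) -> WeightTally:
    """Cumulative weight per feature: sum over folds of the scheme weight of
    each selector that picked it."""
    if not selections:
        raise ValidationError("no fold selections to tally")
    n_folds = max(s.fold_index for s in selections) + 1
    weight_of = {LASSO: scheme.w_lasso, MRMR: scheme.w_mrmr}
    weights: dict[str, int] = {}
    for sel in selections:
        w = weight_of[sel.selector]
        for feature in sel.selected:
            weights[feature] = weights.get(feature, 0) + w
    return WeightTally(scheme=scheme, n_folds=n_folds, weights=weights)


def threshold_features(tally: WeightTally, k: int) -> set[str]:
    """All features with cumulative weight >= k."""
    if not 1 <= k <= tally.max_possible:
        raise ValidationError(
            f"k must be in [1, {tally.max_possible}], got {k}"
        )
    return {f for f, w in tally.weights.items() if w >= k}


def select_final(per_threshold: list[ThresholdResult]) -> ThresholdResult:
    """Maximum accuracy, then minimum feature count, then larger k, then the
    LASSO=1/mRMR=2 scheme, then earlier list position.  Deterministic."""
    scored = [
        (i, r) for i, r in enumerate(per_threshold)
        if r.accuracy is not None and r.n_features > 0
    ]
    if not scored:
        raise ValidationError("no non-empty evaluated threshold results")
    scheme_rank = {s: i for i, s in enumerate(DEFAULT_SCHEMES)}

    def key(item: tuple[int, ThresholdResult]):
        i, r = item
        return (-r.accuracy, r.n_features, -r.k, scheme_rank.get(r.scheme, 99), i)

    return min(scored, key=key)[1]


def sweep(
    matrix: ResponseMatrix,
    selector_config: SelectorConfig | None = None,
    eval_config: EvalConfig | None = None,
    schemes: tuple[WeightScheme, ...] = DEFAULT_SCHEMES,
    n_folds: int = 5,
    seed: int = 0,
    k_max: int | None = None,
) -> SweepResult:
    """Full threshold sweep over both weight schemes.

    The fold selections themselves do not depend on the scheme, so they are
    computed once.  Identical candidate sets (which recur across k and across
    schemes) are evaluated only once and the result reused — the evaluation
    is a pure function of the feature set.  Candidate sets that are empty are
    recorded unevaluated and excluded from the final choice; evaluation
    errors are recorded per cell without aborting the sweep.
    """
    selector_config = selector_config or SelectorConfig()
    eval_config = eval_config or EvalConfig()
    selections = run_fold_selections(matrix, n_folds, selector_config, seed)
    X = matrix.to_frame()
    y = matrix.labels

    cache: dict[frozenset, EvalResult] = {}
    results: list[ThresholdResult] = []
    for scheme in schemes:
        tally = tally_weights(selections, scheme)
        top_k = k_max if k_max is not None else tally.max_possible
        for k in range(1, top_k + 1):
            features = frozenset(threshold_features(tally, k))
            result = ThresholdResult(scheme=scheme, k=k, features=features)
            if features:
                try:
                    if features not in cache:
                        cache[features] = stratified_cv_accuracy(
                            X, y, features, eval_config
                        )
                    ev = cache[features]
                    result.accuracy = ev.accuracy
                    result.balanced_accuracy = ev.balanced_accuracy
                except ValidationError as exc:  # pragma: no cover - defensive
                    result.error = str(exc)
            results.append(result)
    return SweepResult(
        per_threshold=results, chosen=select_final(results), selections=selections
    )


def sweep_to_dict(result: SweepResult) -> dict:
    """JSON-serializable view of a sweep, mirroring the (scheme, k) tables."""

    def row(r: ThresholdResult) -> dict:
        return {
            "scheme": r.scheme.name,
            "k": r.k,
            "n_features": r.n_features,
            "accuracy": r.accuracy,
            "accuracy_pct": None if r.accuracy is None else round(100 * r.accuracy, 3),
            "balanced_accuracy": r.balanced_accuracy,
            "features": sorted(r.features),
            "error": r.error,
        }

    return {
        "per_threshold": [row(r) for r in result.per_threshold],
        "chosen": row(result.chosen),
    }
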