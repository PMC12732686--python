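"""Stratified k-fold Random Forest evaluation and accuracy metrics.

The endpoint is heavily imbalanced (GBM cell lines are a few percent of the
total), so the raw accuracy ACC = (TP + TN) / (TP + TN + FP + FN) sits near
the majority-class rate for any reasonable classifier; balanced accuracy —
the mean of sensitivity and specificity — is reported alongside it to expose
minority-class performance.  Confusion counts are pooled over the folds
(a per-fold-mean mode is available), and accuracies are also rendered as
percentages with three decimals, the display convention used for screen
results of this kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValidationError("confusion counts must sum to >= 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class EvalConfig:
    """Random Forest evaluation settings (5 folds, 100 trees, seed 0)."""

    n_folds: int = 5
    n_trees: int = 100
    seed: int = 0
    pooling: str = "pooled"  # or "fold-mean"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.pooling not in ("pooled", "fold-mean"):
            raise ValidationError("pooling must be 'pooled' or 'fold-mean'")


@dataclass
class EvalResult:
    accuracy: float
    balanced_accuracy: float
    counts: ConfusionCounts

    @property
    def accuracy_pct(self) -> float:
        """Accuracy as a percentage rounded to 3 decimals (e.g. 96.592)."""
        return round(100.0 * self.accuracy, 3)


def accuracy_from_counts(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return (c.tp + c.tn) / c.total


def balanced_accuracy_from_counts(c: ConfusionCounts) -> float:
    """Mean of sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValidationError("balanced accuracy needs both classes present")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def stratified_folds(labels, n_folds: int, seed: int = 0) -> np.ndarray:
    """Fold index per sample; each fold's class counts are within 1 of exact
    proportionality.  Deterministic given the seed."""
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("labels must contain both classes")
    if counts.min() < n_folds:
        raise ValidationError(
            f"smallest class has {counts.min()} members, fewer than "
            f"{n_folds} folds; use fewer folds"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _forest(config: EvalConfig) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )


def stratified_cv_accuracy(
    X: pd.DataFrame,
    y,
    feature_subset,
    config: EvalConfig | None = None,
) -> EvalResult:
    """Cross-validated Random Forest accuracy on a feature subset.

    A fresh forest (fixed seed) is fitted per fold on the training rows
    restricted to ``feature_subset`` and scored on the held-out rows;
    confusion counts are pooled over folds (or metrics averaged per fold in
    ``fold-mean`` mode).
    """
    config = config or EvalConfig()
    features = sorted(feature_subset)
    if not features:
        raise ValidationError("feature_subset must be non-empty")
    absent = [f for f in features if f not in X.columns]
    if absent:
        raise ValidationError(f"features absent from X: {absent}")
    y = np.asarray(y, dtype=int)

    assignment = stratified_folds(y, config.n_folds, config.seed)
    Xs = X[features].to_numpy(dtype=float)
    pooled: ConfusionCounts | None = None
    fold_acc, fold_bacc = [], []
    for fold in range(config.n_folds):
        test = assignment == fold
        model = _forest(config)
        model.fit(Xs[~test], y[~test])
        pred = model.predict(Xs[test])
        c = _confusion(y[test], pred)
        pooled = c if pooled is None else pooled + c
        fold_acc.append(accuracy_from_counts(c))
        if (c.tp + c.fn) > 0 and (c.tn + c.fp) > 0:
            fold_bacc.append(balanced_accuracy_from_counts(c))

    assert pooled is not None
    if config.pooling == "pooled":
        acc = accuracy_from_counts(pooled)
        bacc = balanced_accuracy_from_counts(pooled)
    else:
        acc = float(np.mean(fold_acc))
        bacc = float(np.mean(fold_bacc))
    return EvalResult(accuracy=acc, balanced_accuracy=bacc, counts=pooled)


@dataclass
class FittedModel:
    """A Random Forest fitted on all rows, restricted to one feature set."""

    model: RandomForestClassifier
    features: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(self._restrict(X))

    def predict_proba_positive(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(self._restrict(X))[:, 1]

    def _restrict(self, X: pd.DataFrame) -> np.ndarray:
        absent = [f for f in self.features if f not in X.columns]
        if absent:
            raise ValidationError(f"features absent from X: {absent}")
        return X[self.features].to_numpy(dtype=float)


def fit_final_model(
    X: pd.DataFrame, y, feature_subset, config: EvalConfig | None = None
) -> FittedModel:
    """Deterministic fit on all rows, restricted to ``feature_subset``."""
    config = config or EvalConfig()
    features = sorted(feature_subset)
    if not features:
        raise ValidationError("feature_subset must be non-empty")
    y = np.asarray(y, dtype=int)
    model = _forest(config)
    model.fit(X[features].to_numpy(dtype=float), y)
    return FittedModel(model=model, features=features)
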