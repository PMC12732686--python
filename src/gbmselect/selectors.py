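"""The two per-fold base feature selectors: LASSO and greedy mRMR.

``lasso_select`` fits an L1-penalized linear model of the 0/1 label over a
log-spaced regularization path, picks the penalty by inner stratified
cross-validation, and returns the features with non-negligible coefficients
— a data-driven, possibly empty set.

``mrmr_select`` is the greedy F-test/correlation-quotient (FCQ) variant of
minimum-redundancy-maximum-relevance: relevance is the one-way ANOVA F
statistic of a feature grouped by the class label, redundancy is the mean
absolute Pearson correlation with the already-selected set, and each step
picks the feature maximizing relevance / redundancy.  It returns exactly
``k`` features in pick order, so the result at ``k`` is a prefix of the
result at ``k + 1``.

Both selectors are deterministic given their inputs and seed: columns are
processed in lexicographic order and exact score ties are broken by drug
name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LassoCV
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError

#: Floor on the mean-absolute-correlation redundancy, preventing unstable
#: quotients for features nearly orthogonal to the selected set.
REDUNDANCY_FLOOR = 1e-6


@dataclass(frozen=True)
class SelectorConfig:
    """Settings shared by the per-fold selectors."""

    lasso_path_size: int = 50
    lasso_inner_folds: int = 3
    lasso_coef_threshold: float = 1e-8
    mrmr_k: int = 30
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mrmr_k < 1:
            raise ValidationError("mrmr_k must be >= 1")
        if self.lasso_inner_folds < 2:
            raise ValidationError("lasso_inner_folds must be >= 2")
        if self.lasso_path_size < 1:
            raise ValidationError("lasso_path_size must be >= 1")
        if self.lasso_coef_threshold <= 0:
            raise ValidationError("lasso_coef_threshold must be positive")


def _check_Xy(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    if not isinstance(X, pd.DataFrame):
        raise ValidationError("X must be a pandas DataFrame of drug columns")
    y = np.asarray(y, dtype=int)
    if y.shape != (len(X),):
        raise ValidationError("y length must match X rows")
    if np.isnan(X.to_numpy(dtype=float)).any():
        raise ValidationError("X must be complete (impute first)")
    if len(np.unique(y)) < 2:
        raise ValidationError("y must contain both classes")
    return X, y


def lasso_select(
    X: pd.DataFrame, y, config: SelectorConfig | None = None
) -> set[str]:
    """Features with |coefficient| above threshold at the CV-chosen penalty.

    Columns are sorted lexicographically before the coordinate-descent fit so
    the selected set does not depend on the caller's column order.  With
    ``standardize`` the features are scaled to zero mean / unit variance;
    zero-variance columns are left at zero and thus receive a zero
    coefficient.  May return an empty set.
    """
    config = config or SelectorConfig()
    X, y = _check_Xy(X, y)
    X = X[sorted(X.columns)]
    values = X.to_numpy(dtype=float)

    if config.standardize:
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - mean) / sd
    if (values.std(axis=0) == 0).all():
        return set()

    inner = StratifiedKFold(
        n_splits=config.lasso_inner_folds, shuffle=True, random_state=config.seed
    )
    model = LassoCV(
        alphas=config.lasso_path_size,
        cv=inner,
        random_state=config.seed,
        max_iter=5000,
    )
    model.fit(values, y.astype(float))
    chosen = np.abs(model.coef_) > config.lasso_coef_threshold
    return {name for name, keep in zip(X.columns, chosen) if keep}


def _relevance(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way F statistic per column; zero-variance columns get 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(values, y)
    return np.nan_to_num(f_stat, nan=0.0, posinf=0.0, neginf=0.0)


def mrmr_select(X: pd.DataFrame, y, k: int) -> list[str]:
    """Greedy FCQ selection of exactly ``k`` drug names, in pick order."""
    X, y = _check_Xy(X, y)
    names = sorted(X.columns)
    values = X[names].to_numpy(dtype=float)
    p = values.shape[1]
    if not 1 <= k <= p:
        raise ValidationError(f"k must be in [1, {p}], got {k}")

    relevance = _relevance(values, y)

    # |Pearson correlation| matrix; zero-variance columns correlate 0
    sd = values.std(axis=0)
    safe = sd > 0
    z = (values - values.mean(axis=0)) / np.where(safe, sd, 1.0)
    corr = np.abs(z.T @ z) / len(values)
    corr[~safe, :] = 0.0
    corr[:, ~safe] = 0.0

    selected: list[int] = []
    remaining = list(range(p))
    redundancy_sum = np.zeros(p)
    while len(selected) < k:
        if selected:
            redundancy = np.maximum(
                redundancy_sum / len(selected), REDUNDANCY_FLOOR
            )
            score = relevance / redundancy
        else:
            score = relevance.copy()
        top = max(score[j] for j in remaining)
        # exact ties on score resolve to the lexicographically smallest name
        best = min((j for j in remaining if score[j] == top), key=lambda j: names[j])
        selected.append(best)
        remaining.remove(best)
        redundancy_sum += corr[:, best]
    return [names[j] for j in selected]
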