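"""Multivariate iterative (round-robin regression) imputation of a pivoted
response matrix.

Missing cells are initialized with column means, then each drug column is
regressed in turn on all the others using the rows where it is observed, and
its missing entries are replaced by the regression predictions; the cycle
repeats until the imputed entries stop changing or ``max_iter`` is reached.
The column model is a regularized (Bayesian ridge) linear regression, since
the number of drugs can approach the number of cell lines after pivoting and
ordinary least squares would be ill-posed.  Imputed values are clipped to
each column's observed min/max +/- 3 observed standard deviations to prevent
divergence on near-collinear columns.  Labels are never seen by the imputer.

Imputation is run once on the full matrix by default (the fold-consistent
convention this package follows; the leakage this introduces is documented
in the methods note); a per-fold variant can be built by calling
:func:`iterative_impute` on row subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .exceptions import ValidationError
from .gdsc_io import ResponseMatrix

_ORDERS = {
    # spec order -> sklearn imputation_order; columns are kept
    # lexicographically sorted, so "roman" (left-to-right) is lexicographic.
    "ascending-missingness": "ascending",
    "descending-missingness": "descending",
    "lexicographic": "roman",
}


@dataclass(frozen=True)
class ImputerConfig:
    """Settings of the round-robin imputer.

    ``tol`` is the convergence threshold on the scaled maximum absolute
    change of imputed entries between sweeps.
    """

    max_iter: int = 10
    tol: float = 1e-3
    estimator: str = "bayesian-ridge"
    seed: int = 0
    order: str = "ascending-missingness"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.order not in _ORDERS:
            raise ValidationError(f"order must be one of {sorted(_ORDERS)}")
        if self.estimator != "bayesian-ridge":
            raise ValidationError("estimator must be 'bayesian-ridge'")


def iterative_impute(
    matrix: ResponseMatrix, config: ImputerConfig | None = None
) -> ResponseMatrix:
    """Return a complete copy of ``matrix``; observed entries are untouched.

    Raises on matrices with fewer than two columns or with a column that has
    no observed value at all (such columns carry no information to regress
    on and must be removed explicitly by the caller).
    """
    config = config or ImputerConfig()
    values = matrix.values
    if values.shape[1] < 2:
        raise ValidationError("imputation requires at least 2 drug columns")
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        bad = [matrix.drugs[j] for j in np.flatnonzero(all_missing)]
        raise ValidationError(f"columns with no observed values: {bad}")

    if matrix.is_complete():
        return replace(matrix, values=values.copy())

    obs_min = np.nanmin(values, axis=0)
    obs_max = np.nanmax(values, axis=0)
    obs_sd = np.nanstd(values, axis=0)
    # constant columns have zero spread; widen their clip window trivially
    # so the bounds stay strictly ordered
    obs_sd = np.where(obs_sd > 0, obs_sd, 1e-6 * np.maximum(1.0, np.abs(obs_max)))
    imputer = IterativeImputer(
        estimator=BayesianRidge(),
        max_iter=config.max_iter,
        tol=config.tol,
        imputation_order=_ORDERS[config.order],
        initial_strategy="mean",
        min_value=obs_min - 3 * obs_sd,
        max_value=obs_max + 3 * obs_sd,
        sample_posterior=False,
        random_state=config.seed,
    )
    filled = imputer.fit_transform(values)
    # guarantee observed entries are bit-identical
    observed = ~np.isnan(values)
    filled[observed] = values[observed]
    return replace(matrix, values=filled)


def column_mean_impute(matrix: ResponseMatrix) -> ResponseMatrix:
    """Baseline: replace each missing cell with its column's observed mean."""
    values = matrix.values.copy()
    means = np.nanmean(values, axis=0)
    idx = np.where(np.isnan(values))
    values[idx] = means[idx[1]]
    return replace(matrix, values=values)
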