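"""Weight tallies, threshold semantics, the final-selection rule, and the
full sweep on planted synthetic data."""

import numpy as np
import pytest

from gbmselect.ensemble_weighting import (
    DEFAULT_SCHEMES,
    FoldSelection,
    ThresholdResult,
    WeightScheme,
    WeightTally,
    run_fold_selections,
    select_final,
    sweep,
    tally_weights,
    threshold_features,
)
from gbmselect.exceptions import ValidationError
from gbmselect.selectors import SelectorConfig

from conftest import make_matrix

SCHEME_12 = WeightScheme(w_lasso=1, w_mrmr=2)
SCHEME_21 = WeightScheme(w_lasso=2, w_mrmr=1)


def selections_for(feature_plan):
    """feature_plan: {feature: [(fold, selector), ...]} -> FoldSelection list."""
    by_cell: dict[tuple, list] = {}
    for feature, picks in feature_plan.items():
        for fold, selector in picks:
            by_cell.setdefault((fold, selector), []).append(feature)
    n_folds = 5
    out = []
    for fold in range(n_folds):
        for selector in ("LASSO", "mRMR"):
            out.append(
                FoldSelection(fold, selector, sorted(by_cell.get((fold, selector), [])))
            )
    return out


class TestWeightScheme:
    def test_both_weights_two_rejected(self):
        with pytest.raises(ValidationError):
            WeightScheme(w_lasso=2, w_mrmr=2)

    def test_both_weights_one_rejected(self):
        with pytest.raises(ValidationError):
            WeightScheme(w_lasso=1, w_mrmr=1)


class TestTally:
    def test_picked_by_both_in_all_folds_reaches_fifteen(self):
        plan = {"F": [(f, s) for f in range(5) for s in ("LASSO", "mRMR")]}
        for scheme in (SCHEME_12, SCHEME_21):
            tally = tally_weights(selections_for(plan), scheme)
            assert tally.weights["F"] == 15
            assert tally.max_possible == 15

    def test_single_pick_by_weight_one_selector_scores_one(self):
        plan = {"F": [(2, "LASSO")]}
        tally = tally_weights(selections_for(plan), SCHEME_12)  # LASSO weight 1
        assert tally.weights["F"] == 1

    def test_mrmr_only_three_folds_weight_two_scores_six(self):
        plan = {"F": [(0, "mRMR"), (2, "mRMR"), (4, "mRMR")]}
        tally = tally_weights(selections_for(plan), SCHEME_12)  # mRMR weight 2
        assert tally.weights["F"] == 6

    def test_weights_bounded_by_scheme_and_folds(self, small_imputed):
        selections = run_fold_selections(small_imputed, 5, SelectorConfig(mrmr_k=8))
        for scheme in DEFAULT_SCHEMES:
            tally = tally_weights(selections, scheme)
            assert all(1 <= w <= 15 for w in tally.weights.values())


class TestThreshold:
    def test_threshold_keeps_weights_at_least_k(self):
        tally = WeightTally(SCHEME_12, 5, {"A": 15, "B": 7, "C": 1})
        assert threshold_features(tally, 7) == {"A", "B"}

    def test_k1_is_union_of_all_selections(self):
        tally = WeightTally(SCHEME_12, 5, {"A": 15, "B": 7, "C": 1})
        assert threshold_features(tally, 1) == {"A", "B", "C"}

    def test_k15_requires_unanimous_selection(self):
        plan = {
            "ALL": [(f, s) for f in range(5) for s in ("LASSO", "mRMR")],
            "MOST": [(f, s) for f in range(4) for s in ("LASSO", "mRMR")],
        }
        tally = tally_weights(selections_for(plan), SCHEME_12)
        assert threshold_features(tally, 15) == {"ALL"}

    def test_nesting_and_monotone_counts(self, rng):
        for _ in range(50):
            weights = {
                f"D{j}": int(w) for j, w in enumerate(rng.integers(1, 16, size=40))
            }
            tally = WeightTally(SCHEME_12, 5, weights)
            previous = None
            for k in range(1, 16):
                current = threshold_features(tally, k)
                if previous is not None:
                    assert current <= previous
                previous = current

    def test_k_out_of_range_rejected(self):
        tally = WeightTally(SCHEME_12, 5, {"A": 3})
        for bad in (0, 16):
            with pytest.raises(ValidationError):
                threshold_features(tally, bad)


class TestSelectFinal:
    def result(self, k, acc, n, scheme=SCHEME_12):
        return ThresholdResult(
            scheme=scheme, k=k, features=frozenset(f"F{i}" for i in range(n)),
            accuracy=acc,
        )

    def test_max_accuracy_then_min_features(self):
        results = [
            self.result(5, 0.96592, 36),
            self.result(6, 0.96592, 10),
            self.result(7, 0.96591, 6),
        ]
        chosen = select_final(results)
        assert (chosen.k, chosen.n_features) == (6, 10)

    def test_singleton(self):
        only = self.result(3, 0.9, 4)
        assert select_final([only]) is only

    def test_tie_on_accuracy_and_size_prefers_larger_k(self):
        results = [self.result(4, 0.95, 7), self.result(9, 0.95, 7)]
        assert select_final(results).k == 9

    def test_full_tie_prefers_mrmr_heavy_scheme(self):
        results = [
            self.result(5, 0.95, 7, scheme=SCHEME_21),
            self.result(5, 0.95, 7, scheme=SCHEME_12),
        ]
        assert select_final(results).scheme == SCHEME_12

    def test_all_empty_errors(self):
        empty = ThresholdResult(scheme=SCHEME_12, k=1, features=frozenset())
        with pytest.raises(ValidationError):
            select_final([empty])


class TestRunFoldSelections:
    def test_returns_two_entries_per_fold(self, small_imputed):
        selections = run_fold_selections(small_imputed, 5, SelectorConfig(mrmr_k=8))
        assert len(selections) == 10
        assert {(s.fold_index, s.selector) for s in selections} == {
            (f, s) for f in range(5) for s in ("LASSO", "mRMR")
        }

    def test_deterministic(self, small_imputed):
        config = SelectorConfig(mrmr_k=8)
        a = run_fold_selections(small_imputed, 5, config)
        b = run_fold_selections(small_imputed, 5, config)
        assert [(s.fold_index, s.selector, s.selected) for s in a] == [
            (s.fold_index, s.selector, s.selected) for s in b
        ]

    def test_one_class_matrix_rejected(self, rng):
        m = make_matrix(rng.normal(size=(20, 4)), labels=[0] * 20)
        with pytest.raises(ValidationError):
            run_fold_selections(m, 5)

    def test_incomplete_matrix_rejected(self, small_matrix):
        with pytest.raises(ValidationError, match="complete"):
            run_fold_selections(small_matrix, 5)

    def test_minority_fold_counts_for_33_positives(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(968, 6))
        labels = np.array([1] * 33 + [0] * 935)
        m = make_matrix(values, labels)
        selections = run_fold_selections(m, 5, SelectorConfig(mrmr_k=3))
        assert len(selections) == 10


class TestSweep:
    def test_counts_non_increasing_and_recovery(self, small_imputed, small_dataset):
        result = sweep(small_imputed, SelectorConfig(mrmr_k=8))
        for scheme in DEFAULT_SCHEMES:
            rows = [r for r in result.per_threshold if r.scheme == scheme]
            assert [r.k for r in rows] == list(range(1, 16))
            sizes = [r.n_features for r in rows]
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        # planted drugs recovered by the chosen set
        assert small_dataset.truth_informative <= set(result.chosen.features)

    def test_schemes_coincide_at_k1(self, small_imputed):
        result = sweep(small_imputed, SelectorConfig(mrmr_k=8))
        first = {r.scheme: r for r in result.per_threshold if r.k == 1}
        a, b = (first[s] for s in DEFAULT_SCHEMES)
        assert a.features == b.features
        assert a.accuracy == b.accuracy

    def test_sweep_deterministic(self, small_imputed):
        r1 = sweep(small_imputed, SelectorConfig(mrmr_k=8))
        r2 = sweep(small_imputed, SelectorConfig(mrmr_k=8))
        assert [(r.scheme.name, r.k, sorted(r.features), r.accuracy)
                for r in r1.per_threshold] == [
            (r.scheme.name, r.k, sorted(r.features), r.accuracy)
            for r in r2.per_threshold
        ]
        assert r1.chosen.features == r2.chosen.features
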