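"""Additive per-feature attribution of the final Random Forest.

For each decision tree, a sample's predicted positive-class probability is
the value stored at the leaf it reaches; walking the root-to-leaf path, every
edge changes the running node value by some amount, and that change is
credited to the feature tested at the parent node.  Summed along the path
these credits reconstruct the leaf value exactly, so per sample:

    prediction = base value (root) + sum over features of attribution

Averaging over trees gives the same decomposition for the forest, because a
Random Forest's probability is the mean of its trees' leaf values.  This
path-based decomposition is additive by construction (the "local accuracy"
axiom of additive explanation methods) and deterministic.  The summary ranks
features by mean absolute attribution; the sign summary is the Pearson
correlation between a feature's values and its attributions, capturing the
"high value pushes the prediction up/down" reading of beeswarm plots.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix

from .evaluation import FittedModel
from .exceptions import ValidationError


@dataclass
class AttributionSummary:
    """Features ranked by mean |attribution|, with a sign summary each."""

    ranked: list[tuple[str, float, float]]

    @property
    def features(self) -> list[str]:
        return [name for name, _, _ in self.ranked]


def _tree_contribution_map(tree) -> tuple[csr_matrix, float]:
    """Sparse node -> feature contribution map for one fitted tree.

    Entry (node, feature) holds value(node) - value(parent) for the feature
    split at the parent; multiplying the decision-path indicator matrix by
    this map accumulates each sample's path deltas per feature.
    """
    t = tree.tree_
    value = t.value[:, 0, 1]  # positive-class fraction per node
    n_nodes = t.node_count
    parent = np.full(n_nodes, -1)
    for node in range(n_nodes):
        for child in (t.children_left[node], t.children_right[node]):
            if child != -1:
                parent[child] = node
    rows, cols, data = [], [], []
    for node in range(n_nodes):
        p = parent[node]
        if p == -1:
            continue
        rows.append(node)
        cols.append(t.feature[p])
        data.append(value[node] - value[p])
    mat = csr_matrix(
        (data, (rows, cols)), shape=(n_nodes, t.n_features)
    )
    return mat, float(value[0])


def compute_attributions(
    fitted: FittedModel, X: pd.DataFrame
) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature attributions of P(class 1) and the base value.

    Satisfies ``base + attributions.sum(axis=1) == predict_proba`` exactly
    (up to float round-off).
    """
    Xv = fitted._restrict(X)
    n, p = Xv.shape
    contrib = np.zeros((n, p))
    base = 0.0
    estimators = fitted.model.estimators_
    for tree in estimators:
        path = tree.decision_path(Xv)  # n x nodes indicator
        cmap, root_value = _tree_contribution_map(tree)
        contrib += np.asarray((path @ cmap).todense())
        base += root_value
    n_trees = len(estimators)
    return contrib / n_trees, base / n_trees


def attribution_summary(fitted: FittedModel, X: pd.DataFrame) -> AttributionSummary:
    """Rank the model's features by mean absolute attribution on ``X``."""
    missing = [f for f in fitted.features if f not in X.columns]
    if missing:
        raise ValidationError(f"features absent from X: {missing}")
    contrib, _ = compute_attributions(fitted, X)
    Xv = X[fitted.features].to_numpy(dtype=float)

    entries = []
    for j, name in enumerate(fitted.features):
        mean_abs = float(np.abs(contrib[:, j]).mean())
        x, a = Xv[:, j], contrib[:, j]
        if x.std() > 0 and a.std() > 0:
            sign = float(np.corrcoef(x, a)[0, 1])
        else:
            sign = 0.0
        entries.append((name, mean_abs, sign))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return AttributionSummary(ranked=entries)


def export_summary_plot(summary: AttributionSummary, path) -> None:
    """Write a bar plot of the ranking as PNG plus a CSV alongside it.

    ``path`` names the image; the CSV gets the same stem with a ``.csv``
    suffix.  Deterministic given the summary.
    """
    if not summary.ranked:
        raise ValidationError("summary is empty")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [n for n, _, _ in summary.ranked]
    magnitudes = [m for _, m, _ in summary.ranked]
    signs = [s for _, _, s in summary.ranked]
    colors = ["#d62728" if s >= 0 else "#1f77b4" for s in signs]

    fig, ax = plt.subplots(figsize=(7, 0.35 * len(names) + 1.5))
    ax.barh(range(len(names))[::-1], magnitudes, color=colors)
    ax.set_yticks(range(len(names))[::-1], names)
    ax.set_xlabel("mean |attribution| on P(positive class)")
    ax.set_title("Feature attribution ranking (red: high value pushes up)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    csv_path = str(path).rsplit(".", 1)[0] + ".csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "feature", "mean_abs_attribution", "sign_correlation"])
        for rank, (name, mag, sign) in enumerate(summary.ranked, start=1):
            writer.writerow([rank, name, f"{mag:.10g}", f"{sign:.10g}"])
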