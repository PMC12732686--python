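"""Synthetic GDSC-shaped drug-response data with planted ground truth.

Real GDSC screens are class-imbalanced (roughly 3-4% of cell lines are GBM),
carry per-drug missingness and replicate measurements, and drug responses are
correlated across compounds that share mechanisms.  The generator emulates
these properties on a known ground truth so every downstream stage —
pivoting, imputation, selection, weighting, evaluation — can be tested
without external downloads.

Statistical model
-----------------
Per cell line a binary label is drawn Bernoulli(``positive_fraction``).  A
latent response matrix is drawn from a block-diagonal Gaussian: drugs are
grouped into consecutive blocks of ``block_size`` with pairwise correlation
``block_rho`` (equicorrelation, sampled via a shared block factor).  The
``n_informative`` planted drugs — one per block, spread across distinct
blocks so the planted signals are not mutually redundant — receive an
additive ``effect_size`` shift for label-1 cell lines on the two sensitivity
metrics (LN_IC50 down, i.e. more potent, and AUC down with it); RMSE and
Z_SCORE are pure noise transforms carrying no class signal, matching their
semantics as a curve-fit-quality value and a normalization.  Each drug gets
an MCAR missing rate drawn uniformly from ``missing_rate_range`` applied at
the (cell line, drug) level, and a ``replicate_rate`` fraction of observed
pairs is emitted twice with independent measurement noise to exercise mean
aggregation.

One RNG stream (``numpy.random.default_rng(seed)``) is consumed in a fixed,
documented order — labels, latents, missingness, replicates — so identical
specs produce byte-identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .gdsc_io import METRICS, DrugResponseRecord

# Non-positive tissue labels cycled over label-0 cell lines.
_OTHER_TISSUES = ("BRCA", "LUAD", "COAD", "SKCM", "PAAD", "OV", "LAML")

_REPLICATE_NOISE_SD = 0.05  # on the latent scale, before metric transforms


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the shape of the screens this package targets: ~3.4%
    positive cell lines, a planted effect of two latent standard deviations
    on five informative drugs, moderate block correlation and per-drug MCAR
    missingness between 5% and 40%.
    """

    n_cell_lines: int = 968
    n_drugs: int = 120
    n_informative: int = 5
    positive_fraction: float = 0.034
    effect_size: float = 2.0
    block_size: int = 10
    block_rho: float = 0.5
    missing_rate_range: tuple[float, float] = (0.05, 0.40)
    replicate_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_cell_lines >= 1, "n_cell_lines must be positive"),
            (self.n_drugs >= 1, "n_drugs must be positive"),
            (0 <= self.n_informative <= self.n_drugs,
             "n_informative must be in [0, n_drugs]"),
            (0 < self.positive_fraction < 1,
             "positive_fraction must be in (0, 1)"),
            (self.effect_size >= 0, "effect_size must be non-negative"),
            (self.block_size >= 1, "block_size must be positive"),
            (0 <= self.block_rho < 1, "block_rho must be in [0, 1)"),
            (0 <= self.missing_rate_range[0] <= self.missing_rate_range[1] < 1,
             "missing_rate_range must satisfy 0 <= lower <= upper < 1"),
            (0 <= self.replicate_rate < 1, "replicate_rate must be in [0, 1)"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValidationError(message)


@dataclass
class SyntheticDataset:
    """Generated records plus the ground truth used to score recovery."""

    spec: SyntheticSpec
    records: list[DrugResponseRecord]
    truth_informative: set[str]
    truth_labels: dict[str, int]
    truth_missing_rates: dict[str, float] = field(default_factory=dict)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.truth_labels)


def _drug_names(n: int) -> list[str]:
    return [f"DRUG_{i:04d}" for i in range(n)]


def _cell_line_names(n: int) -> list[str]:
    return [f"CL_{i:04d}" for i in range(n)]


def informative_drugs(spec: SyntheticSpec) -> list[str]:
    """The planted drug names: the first drug of each successive block, then
    (if more informative drugs than blocks) the second of each block, etc."""
    names = _drug_names(spec.n_drugs)
    n_blocks = math.ceil(spec.n_drugs / spec.block_size)
    order: list[int] = []
    for offset in range(spec.block_size):
        for b in range(n_blocks):
            j = b * spec.block_size + offset
            if j < spec.n_drugs:
                order.append(j)
    return [names[j] for j in order[: spec.n_informative]]


def _block_latents(rng: np.random.Generator, n: int, spec: SyntheticSpec) -> np.ndarray:
    """n x n_drugs standard-normal latents with equicorrelated blocks."""
    p, bs, rho = spec.n_drugs, spec.block_size, spec.block_rho
    latent = np.empty((n, p))
    sqrt_rho, sqrt_res = math.sqrt(rho), math.sqrt(1.0 - rho)
    for start in range(0, p, bs):
        width = min(bs, p - start)
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        latent[:, start : start + width] = sqrt_rho * shared + sqrt_res * noise
    return latent


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a dataset under ``spec``; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    cells = _cell_line_names(spec.n_cell_lines)
    drugs = _drug_names(spec.n_drugs)
    informative = informative_drugs(spec)
    info_idx = np.array([drugs.index(d) for d in informative], dtype=int)

    # 1. labels
    labels = (rng.random(spec.n_cell_lines) < spec.positive_fraction).astype(int)

    # 2. latents (block-correlated base + independent noise for the
    #    signal-free metrics)
    latent = _block_latents(rng, spec.n_cell_lines, spec)
    shifted = latent.copy()
    if len(info_idx):
        shifted[np.ix_(labels == 1, info_idx)] -= spec.effect_size
    eps_auc = rng.standard_normal(latent.shape)
    eps_rmse = rng.standard_normal(latent.shape)
    eps_z = rng.standard_normal(latent.shape)

    # metric transforms: signal on LN_IC50 and AUC only
    ln_ic50 = 2.0 + shifted
    auc = 0.80 + 0.07 * shifted + 0.03 * eps_auc
    rmse = np.abs(0.08 + 0.03 * eps_rmse)
    z_score = eps_z

    # 3. per-drug MCAR missingness, applied at the (cell line, drug) level
    lo, hi = spec.missing_rate_range
    rates = rng.uniform(lo, hi, size=spec.n_drugs)
    observed = rng.random((spec.n_cell_lines, spec.n_drugs)) >= rates[None, :]

    # 4. replicates: a fraction of observed pairs measured twice
    replicate = rng.random((spec.n_cell_lines, spec.n_drugs)) < spec.replicate_rate
    rep_noise = rng.standard_normal((spec.n_cell_lines, spec.n_drugs))

    tissue = [
        "GBM" if labels[i] else _OTHER_TISSUES[i % len(_OTHER_TISSUES)]
        for i in range(spec.n_cell_lines)
    ]

    metric_mats = {"LN_IC50": ln_ic50, "AUC": auc, "RMSE": rmse, "Z_SCORE": z_score}
    records: list[DrugResponseRecord] = []
    for i, cl in enumerate(cells):
        for j, drug in enumerate(drugs):
            if observed[i, j]:
                values = {m: float(metric_mats[m][i, j]) for m in METRICS}
            else:
                values = {m: math.nan for m in METRICS}
            records.append(
                DrugResponseRecord(
                    cell_line_id=cl,
                    drug_name=drug,
                    tissue_label=tissue[i],
                    metric_values=values,
                )
            )
            if observed[i, j] and replicate[i, j]:
                delta = _REPLICATE_NOISE_SD * rep_noise[i, j]
                rep_values = {
                    "LN_IC50": float(ln_ic50[i, j] + delta),
                    "AUC": float(auc[i, j] + 0.07 * delta),
                    "RMSE": float(abs(rmse[i, j] + 0.03 * delta)),
                    "Z_SCORE": float(z_score[i, j] + delta),
                }
                records.append(
                    DrugResponseRecord(
                        cell_line_id=cl,
                        drug_name=drug,
                        tissue_label=tissue[i],
                        metric_values=rep_values,
                    )
                )

    return SyntheticDataset(
        spec=spec,
        records=records,
        truth_informative=set(informative),
        truth_labels={cl: int(labels[i]) for i, cl in enumerate(cells)},
        truth_missing_rates={drugs[j]: float(rates[j]) for j in range(spec.n_drugs)},
    )


def write_gdsc_like(dataset: SyntheticDataset, path) -> None:
    """Write records as a CSV in the default GDSC bulk-download dialect."""
    rows = [
        {
            "CELL_LINE_NAME": r.cell_line_id,
            "DRUG_NAME": r.drug_name,
            "TCGA_DESC": r.tissue_label,
            **{m: r.metric_values.get(m, math.nan) for m in METRICS},
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows, columns=["CELL_LINE_NAME", "DRUG_NAME", "TCGA_DESC", *METRICS]).to_csv(
        path, index=False
    )


def write_truth(dataset: SyntheticDataset, path) -> None:
    """Write the ground truth (informative drugs, labels, rates) as JSON."""
    payload = {
        "spec": asdict(dataset.spec),
        "truth_informative": sorted(dataset.truth_informative),
        "truth_labels": dataset.truth_labels,
        "truth_missing_rates": dataset.truth_missing_rates,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
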