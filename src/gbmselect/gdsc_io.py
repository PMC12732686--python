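"""Reading GDSC-style long drug-response tables and pivoting them to
cell-line x drug matrices.

The GDSC bulk downloads ship one row per (cell line, drug) measurement with
the four summary metrics of the fitted dose-response curve: ``LN_IC50``,
``AUC``, ``RMSE`` and ``Z_SCORE``.  This module parses that long format into
:class:`DrugResponseRecord` lists, pivots one metric at a time into a
:class:`ResponseMatrix` (mean-aggregating replicate measurements), attaches a
binary label per cell line (positive tissue label, e.g. ``GBM``, versus all
others) and audits per-drug missingness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical metric names, in GDSC bulk-download order.
METRICS = ("LN_IC50", "AUC", "RMSE", "Z_SCORE")

#: Column used for labels when a matrix is exported to CSV.
LABEL_COLUMN = "LABEL"


@dataclass(frozen=True)
class DialectConfig:
    """Maps canonical fields to physical column names of a long CSV.

    Defaults follow the cancerrxgene.org bulk-download headers, where the
    tissue column is the TCGA classification.
    """

    cell_line: str = "CELL_LINE_NAME"
    drug: str = "DRUG_NAME"
    tissue: str = "TCGA_DESC"
    metrics: dict[str, str] = field(
        default_factory=lambda: {m: m for m in METRICS}
    )


@dataclass
class DrugResponseRecord:
    """One long-format measurement of a drug on a cell line.

    ``metric_values`` maps canonical metric names to floats; a missing
    measurement is either an absent key or a NaN value.
    """

    cell_line_id: str
    drug_name: str
    tissue_label: str
    metric_values: dict[str, float]

    def __post_init__(self) -> None:
        if not self.cell_line_id or not self.drug_name:
            raise ValidationError("cell_line_id and drug_name must be non-empty")
        unknown = set(self.metric_values) - set(METRICS)
        if unknown:
            raise ValidationError(f"unknown metric names: {sorted(unknown)}")

    def value(self, metric: str) -> float:
        """Value of ``metric``, NaN when missing."""
        v = self.metric_values.get(metric, math.nan)
        return math.nan if v is None else float(v)


@dataclass
class ResponseMatrix:
    """A pivoted cell-line x drug matrix for one sensitivity metric.

    ``values`` holds floats with NaN marking missing cells; ``labels`` is the
    binary endpoint (1 = positive tissue, e.g. GBM).  Rows and columns are
    kept lexicographically sorted so downstream fold assignment and weight
    tallies are reproducible.
    """

    metric: str
    cell_lines: list[str]
    drugs: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.values.shape
        if n != len(self.cell_lines) or p != len(self.drugs):
            raise ValidationError("values shape inconsistent with row/column names")
        if self.labels.shape != (n,):
            raise ValidationError("labels length inconsistent with cell lines")
        if len(set(self.cell_lines)) != n:
            raise ValidationError("duplicate cell-line ids")
        if len(set(self.drugs)) != p:
            raise ValidationError("duplicate drug names")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0/1")

    @property
    def mask(self) -> np.ndarray:
        """Boolean missingness mask, True where a cell is missing."""
        return np.isnan(self.values)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def to_frame(self) -> pd.DataFrame:
        """Feature DataFrame (no label column), indexed by cell line."""
        return pd.DataFrame(self.values, index=self.cell_lines, columns=self.drugs)

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_positive == len(self.labels):
            raise ValidationError(
                "both classes must be present before cross-validation"
            )


@dataclass
class MissingnessReport:
    """Per-drug missing-value ratios plus the worst offenders."""

    per_drug_ratio: dict[str, float]
    top_n: list[tuple[str, float]]


def read_gdsc_table(
    path, dialect: DialectConfig | None = None
) -> list[DrugResponseRecord]:
    """Parse a long-format GDSC-style CSV into records.

    Unparseable metric cells become missing values; rows without a cell-line
    id or drug name are dropped (a count is logged).  Raises
    :class:`SchemaError` when mandatory columns are absent.
    """
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path, dtype=str)
    mandatory = [dialect.cell_line, dialect.drug]
    absent = [c for c in mandatory if c not in df.columns]
    if absent:
        raise SchemaError(f"missing mandatory columns: {absent}")

    records: list[DrugResponseRecord] = []
    n_dropped = 0
    tissue_col = dialect.tissue if dialect.tissue in df.columns else None
    metric_cols = {m: c for m, c in dialect.metrics.items() if c in df.columns}
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        cl = row.get(dialect.cell_line)
        drug = row.get(dialect.drug)
        if not isinstance(cl, str) or not cl.strip() or not isinstance(drug, str) or not drug.strip():
            n_dropped += 1
            continue
        values: dict[str, float] = {}
        for metric, col in metric_cols.items():
            raw = row.get(col)
            try:
                values[metric] = float(raw)
            except (TypeError, ValueError):
                values[metric] = math.nan
        tissue = row.get(tissue_col) if tissue_col else ""
        records.append(
            DrugResponseRecord(
                cell_line_id=cl.strip(),
                drug_name=drug.strip(),
                tissue_label=(tissue or "").strip(),
                metric_values=values,
            )
        )
    if n_dropped:
        logger.info("dropped %d rows lacking cell-line id or drug name", n_dropped)
    return records


def pivot_mean(
    records: list[DrugResponseRecord],
    metric: str,
    positive_tissue_label: str = "GBM",
) -> ResponseMatrix:
    """Pivot long records into a cell-line x drug matrix for one metric.

    Replicate measurements of a (cell line, drug) pair are combined with the
    arithmetic mean; a cell is missing iff no non-missing measurement exists.
    A cell line is labelled 1 iff any of its records carries the positive
    tissue label (case-insensitive, trimmed).  Conflicting tissue labels for
    one cell line raise an error rather than being silently resolved.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if not records:
        raise ValidationError("no records to pivot")

    df = pd.DataFrame(
        {
            "cell_line": [r.cell_line_id for r in records],
            "drug": [r.drug_name for r in records],
            "tissue": [r.tissue_label.strip().upper() for r in records],
            "value": [r.value(metric) for r in records],
        }
    )
    conflicting = (
        df.groupby("cell_line")["tissue"].nunique(dropna=False).loc[lambda s: s > 1]
    )
    if len(conflicting):
        raise ValidationError(
            f"conflicting tissue labels for cell lines: {sorted(conflicting.index)}"
        )

    pivot = df.pivot_table(
        index="cell_line", columns="drug", values="value", aggfunc="mean"
    )
    # pivot_table drops cell lines / drugs whose values are all missing;
    # reindex against the full id sets so they stay visible downstream.
    cell_lines = sorted(df["cell_line"].unique())
    drugs = sorted(df["drug"].unique())
    pivot = pivot.reindex(index=cell_lines, columns=drugs)

    positive = positive_tissue_label.strip().upper()
    tissue_of = df.drop_duplicates("cell_line").set_index("cell_line")["tissue"]
    labels = np.array([int(tissue_of[cl] == positive) for cl in cell_lines])

    return ResponseMatrix(
        metric=metric,
        cell_lines=cell_lines,
        drugs=drugs,
        values=pivot.to_numpy(dtype=float),
        labels=labels,
    )


def missingness_report(matrix: ResponseMatrix, top_n: int = 20) -> MissingnessReport:
    """Per-drug missingness ratios, with the ``top_n`` most-missing drugs.

    Ties in ratio are broken lexicographically by drug name.
    """
    if top_n < 0:
        raise ValidationError("top_n must be non-negative")
    n_rows = len(matrix.cell_lines)
    ratios = {
        drug: float(np.isnan(matrix.values[:, j]).sum()) / n_rows
        for j, drug in enumerate(matrix.drugs)
    }
    ranked = sorted(ratios.items(), key=lambda kv: (-kv[1], kv[0]))
    return MissingnessReport(per_drug_ratio=ratios, top_n=ranked[:top_n])


def write_matrix_csv(matrix: ResponseMatrix, path) -> None:
    """Export a matrix as CSV: one row per cell line, drugs as columns plus a
    trailing label column."""
    df = matrix.to_frame()
    df[LABEL_COLUMN] = matrix.labels
    df.to_csv(path, index_label="cell_line")


def read_matrix_csv(path, metric: str) -> ResponseMatrix:
    """Inverse of :func:`write_matrix_csv`."""
    df = pd.read_csv(path, index_col="cell_line")
    if LABEL_COLUMN not in df.columns:
        raise SchemaError(f"matrix CSV lacks the {LABEL_COLUMN!r} column")
    labels = df.pop(LABEL_COLUMN).to_numpy(dtype=int)
    return ResponseMatrix(
        metric=metric,
        cell_lines=[str(i) for i in df.index],
        drugs=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        labels=labels,
    )
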