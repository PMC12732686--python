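"""End-to-end orchestration: pivot -> impute -> sweep -> explain.

One run handles one sensitivity metric (the four metrics are analyzed
separately); a convenience loop over all four is exposed by the CLI.  Every
run writes a manifest with a configuration hash, library versions and
per-stage shapes so a run can be reproduced byte-identically from its
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .attribution import attribution_summary, export_summary_plot
from .ensemble_weighting import DEFAULT_SCHEMES, SweepResult, sweep, sweep_to_dict
from .evaluation import EvalConfig, fit_final_model
from .exceptions import ValidationError
from .gdsc_io import (
    METRICS,
    DialectConfig,
    missingness_report,
    pivot_mean,
    read_gdsc_table,
    write_matrix_csv,
)
from .imputation import ImputerConfig, iterative_impute
from .selectors import SelectorConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All settings of one run, with the package defaults baked in."""

    metric: str = "AUC"
    positive_label: str = "GBM"
    n_folds: int = 5
    seed: int = 0
    dialect: DialectConfig = field(default_factory=DialectConfig)
    imputer: ImputerConfig = field(default_factory=ImputerConfig)
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValidationError(
                f"unknown metric {self.metric!r}; expected one of {METRICS}"
            )
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")


def config_from_yaml(path) -> PipelineConfig:
    """Build a config from a YAML file; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = {}
    for key in ("metric", "positive_label", "n_folds", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "dialect" in raw:
        kwargs["dialect"] = DialectConfig(**raw["dialect"])
    if "imputer" in raw:
        kwargs["imputer"] = ImputerConfig(**raw["imputer"])
    if "selector" in raw:
        kwargs["selector"] = SelectorConfig(**raw["selector"])
    if "evaluation" in raw:
        kwargs["evaluation"] = EvalConfig(**raw["evaluation"])
    return PipelineConfig(**kwargs)


def _config_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, input_csv, out_dir) -> dict:
    """Run the full method on one long-format CSV; returns the manifest.

    Artifacts written to ``out_dir``: the pivoted matrix, the imputed
    matrix, the missingness report, the sweep table, the chosen feature set,
    the attribution ranking (CSV + PNG) and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    logger.info("stage=read input=%s", input_csv)
    records = read_gdsc_table(input_csv, config.dialect)
    stages["read"] = {"n_records": len(records)}

    logger.info("stage=pivot metric=%s", config.metric)
    matrix = pivot_mean(records, config.metric, config.positive_label)
    stages["pivot"] = {
        "n_cell_lines": len(matrix.cell_lines),
        "n_drugs": len(matrix.drugs),
        "n_positive": matrix.n_positive,
        "missing_cells": int(matrix.mask.sum()),
    }
    write_matrix_csv(matrix, out / "matrix.csv")
    report = missingness_report(matrix)
    (out / "missingness.json").write_text(
        json.dumps(
            {"per_drug_ratio": report.per_drug_ratio, "top_n": report.top_n},
            indent=2,
        )
    )

    logger.info("stage=impute order=%s", config.imputer.order)
    imputed = iterative_impute(matrix, config.imputer)
    stages["impute"] = {"missing_cells_after": int(imputed.mask.sum())}
    write_matrix_csv(imputed, out / "matrix_imputed.csv")

    logger.info("stage=sweep schemes=%d", len(DEFAULT_SCHEMES))
    result: SweepResult = sweep(
        imputed,
        selector_config=config.selector,
        eval_config=config.evaluation,
        n_folds=config.n_folds,
        seed=config.seed,
    )
    sweep_dict = sweep_to_dict(result)
    (out / "sweep.json").write_text(json.dumps(sweep_dict, indent=2))
    chosen = result.chosen
    stages["sweep"] = {
        "n_cells": len(result.per_threshold),
        "chosen_k": chosen.k,
        "chosen_scheme": chosen.scheme.name,
        "chosen_n_features": chosen.n_features,
        "chosen_accuracy": chosen.accuracy,
    }
    (out / "chosen_features.json").write_text(
        json.dumps(sweep_dict["chosen"], indent=2)
    )

    logger.info("stage=explain n_features=%d", chosen.n_features)
    fitted = fit_final_model(
        imputed.to_frame(), imputed.labels, chosen.features, config.evaluation
    )
    summary = attribution_summary(fitted, imputed.to_frame())
    export_summary_plot(summary, out / "attribution_summary.png")
    stages["explain"] = {"top_feature": summary.ranked[0][0]}

    manifest = {
        "package": "gbmselect",
        "config": _config_dict(config),
        "config_hash": _config_hash(config),
        "input": str(input_csv),
        "stages": stages,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _versions() -> dict:
    import numpy, pandas, scipy, sklearn  # noqa: PLC0415

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
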