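"""End-to-end regulon validation workflow.

Stages: import expression data and candidate network, smooth each profile,
remove no-change genes, remove constant-synthesis targets, fit the
regulation model per surviving edge, classify fits, and optionally apply
manual overrides. The run report records the gene/edge counts at every
stage and all effective parameters; identical config and seed give
byte-identical outputs.

The human-inspection steps of the interactive workflow are replaced by
diagnostic plot files (one per fitted edge) and an overrides TSV that can
flip individual classifications.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .fitting import (
    AnnealingConfig,
    ErrorMarginSpec,
    FitSettings,
    Label,
    apply_overrides,
    evaluate_edges,
)

logger = logging.getLogger(__name__)


@dataclass
class WorkflowConfig:
    """Everything a reproducible run needs.

    Paths are resolved at run time; numeric fields default to the library
    defaults (df = half the time points, dense resolution 100, error band
    10% relative with a 2.5%-of-max floor, threshold 0.8, c = dense/10).
    """

    expression_path: str | Path = ""
    network_path: str | Path = ""
    expression_format: str = "delimited"  # or "soft"
    sample_times: dict[str, float] | None = None
    df: int | None = None
    resolution: int | None = None
    e_minimal: float | None = None
    e_absolute: float | None = None
    e_relative: float | None = None
    fit_quality_threshold: float = 0.8
    c: float | None = None
    restarts: int = 128
    iterations: int = 1000
    seed: int = 0
    overrides_path: str | Path | None = None
    results_path: str | Path | None = None
    report_path: str | Path | None = None
    plots_dir: str | Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def margin(self) -> ErrorMarginSpec | None:
        if self.e_minimal is None and self.e_absolute is None and self.e_relative is None:
            return None
        return ErrorMarginSpec(
            e_minimal=self.e_minimal or 0.0,
            e_absolute=self.e_absolute or 0.0,
            e_relative=self.e_relative if self.e_relative is not None else 0.0,
        )

    def fit_settings(self) -> FitSettings:
        return FitSettings(
            df=self.df,
            resolution=self.resolution,
            margin=self.margin(),
            fit_quality_threshold=self.fit_quality_threshold,
            c=self.c,
            annealing=AnnealingConfig(
                restarts=self.restarts, iterations=self.iterations, seed=self.seed
            ),
        )


def _load_dataset(config: WorkflowConfig) -> rio.ExpressionSet:
    path = Path(config.expression_path)
    if not path.exists():
        raise FileNotFoundError(f"import stage: expression file not found: {path}")
    if config.expression_format == "soft":
        return rio.read_soft(path, sample_times=config.sample_times)
    return rio.read_delimited(path)


def run_workflow(
    config: WorkflowConfig,
    *,
    dataset: rio.ExpressionSet | None = None,
    network: rio.CandidateNetwork | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Execute the full pipeline; returns (result table, run report).

    *dataset*/*network* may be passed in memory to skip the import stage
    (the report then records them as preloaded).
    """
    t_start = time.perf_counter()
    report: dict[str, Any] = {"stages": {}, "parameters": {}}

    if dataset is None:
        dataset = _load_dataset(config)
    if network is None:
        path = Path(config.network_path)
        if not path.exists():
            raise FileNotFoundError(f"import stage: network file not found: {path}")
        network = rio.read_network(path)
    network.resolve(dataset)
    report["stages"]["imported"] = {
        "genes": dataset.n_genes,
        "time_points": dataset.grid.n,
        "edges": len(network.edges),
    }

    settings = config.fit_settings()
    dense, margin, classification, reg_spec = settings.resolve(dataset)
    report["parameters"] = {
        "df": settings.df,
        "dense_resolution": dense.resolution,
        "e_minimal": margin.e_minimal,
        "e_absolute": margin.e_absolute,
        "e_relative": margin.e_relative,
        "fit_quality_threshold": classification.fit_quality_threshold,
        "c": reg_spec.c,
        "restarts": settings.annealing.restarts,
        "iterations": settings.annealing.iterations,
        "seed": settings.annealing.seed,
    }

    table = evaluate_edges(dataset, network, settings)
    counts = table["label"].value_counts().to_dict() if len(table) else {}
    notes = (
        int((table["note"] == "regulator shows no change").sum()) if len(table) else 0
    )
    report["stages"]["screened"] = {
        "no_change_edges": int(counts.get(str(Label.NO_CHANGE), 0)),
        "no_change_regulator_edges": notes,
        "constant_synthesis_edges": int(counts.get(str(Label.CONSTANT_SYNTHESIS), 0)),
    }
    report["stages"]["fitted"] = {
        "good_fit": int(counts.get(str(Label.GOOD_FIT), 0)),
        "no_fit": int(counts.get(str(Label.NO_FIT), 0)),
    }

    manual = 0
    if config.overrides_path:
        overrides = rio.read_overrides(config.overrides_path)
        table = apply_overrides(table, overrides)
        manual = len(overrides)
    report["stages"]["overridden"] = {"manual_decisions": manual}

    if config.plots_dir:
        from . import plots

        n = plots.plot_edges(
            dataset, table, settings, Path(config.plots_dir)
        )
        report["stages"]["plots"] = {"written": n}

    report["elapsed_seconds"] = round(time.perf_counter() - t_start, 3)

    if config.results_path:
        rio.write_results(table, config.results_path)
    if config.report_path:
        Path(config.report_path).write_text(render_report(report))
    return table, report


def render_report(report: Mapping[str, Any]) -> str:
    lines = ["regulonfit run report", "====================", ""]
    lines.append("parameters:")
    for k, v in report.get("parameters", {}).items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    for stage, info in report.get("stages", {}).items():
        lines.append(f"{stage}:")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
    if "elapsed_seconds" in report:
        lines.append("")
        lines.append(f"elapsed_seconds: {report['elapsed_seconds']}")
    return "\n".join(lines) + "\n"
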