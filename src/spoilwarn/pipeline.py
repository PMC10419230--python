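"""End-to-end orchestration: simulate -> select -> fit -> compare -> monitor.

This module holds the computations behind the command-line interface so
that scripts and tests can drive the full analysis programmatically.  The
model-comparison table mirrors the conventional chemometrics layout: one
row per selector-PLS combination with Rc, RMSEC, Rp, RMSEP and the number
of selected variables.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as swio
from .chemometrics import (
    CVConfig,
    EvaluationReport,
    PLSModel,
    evaluate,
    fit_pls,
    kfold_rmsecv,
    split_calibration_prediction,
)
from .data_model import CHANNELS, Dataset, flatten_record, index_to_channel
from .selection import SelectionResult, run_all_selectors
from .simulate import WarehouseSimConfig, simulate_dataset
from .warning import (
    WarningModel,
    export_model,
    grade,
    render_equation,
    score,
)

logger = logging.getLogger("spoilwarn")

#: Per-algorithm cap on PLS components for the final refit.
MAX_COMPONENTS_BY_ALGORITHM = {"GA": 15, "SA": 12, "ACO": 15, "CARS": 15}

MODEL_ROW_ORDER = ("GA", "SA", "ACO", "CARS")


@dataclass
class TrainedModel:
    """One selector's outcome: selection, refit PLS and its statistics."""

    selection: SelectionResult
    pls: PLSModel
    report: EvaluationReport


@dataclass
class MonitoringEntry:
    """Per-acquisition monitoring record."""

    timestamp: str
    warehouse_id: str
    day: int
    channel_means: dict[str, float]
    score: float
    grade: str
    in_range: bool


def cmd_simulate(config: WarehouseSimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a warehouse study and write dataset CSV + ground truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    dataset, truth = simulate_dataset(config)
    dataset_path = out_dir / "dataset.csv"
    truth_path = out_dir / "ground_truth.json"
    swio.write_dataset(dataset, dataset_path)
    swio.write_ground_truth_json(truth, truth_path)
    logger.info(
        "simulated %d samples x %d features (seed %d) in %.1fs -> %s",
        dataset.n_samples, dataset.n_features, config.seed,
        time.perf_counter() - t0, dataset_path,
    )
    return {"dataset": dataset_path, "ground_truth": truth_path}


def fit_selection_model(
    dataset: Dataset, selection: SelectionResult, cv: CVConfig
) -> TrainedModel:
    """Refit PLS on a selection (calibration rows) and evaluate it."""
    cap = MAX_COMPONENTS_BY_ALGORITHM.get(selection.algorithm, cv.max_components)
    cal = dataset.rows("calibration")
    X, y = dataset.features[cal], dataset.labels[cal]
    cv_eff = CVConfig(
        n_folds=cv.n_folds,
        shuffle_seed=cv.shuffle_seed,
        max_components=min(cv.max_components, cap),
    )
    best_k = kfold_rmsecv(X, y, selection.selected_indices, cv_eff).best_n_components
    pls = fit_pls(X, y, best_k, feature_indices=selection.selected_indices)
    report = evaluate(pls, dataset)
    return TrainedModel(selection=selection, pls=pls, report=report)


def comparison_table(trained: dict[str, TrainedModel]) -> pd.DataFrame:
    """Four-row model comparison: Rc, RMSEC, Rp, RMSEP, n_variables."""
    rows = []
    for name in MODEL_ROW_ORDER:
        if name not in trained:
            continue
        t = trained[name]
        rows.append(
            {
                "Model": f"{name}-PLS",
                "Rc": t.report.r_calibration,
                "RMSEC": t.report.rmse_calibration,
                "Rp": t.report.r_prediction,
                "RMSEP": t.report.rmse_prediction,
                "n_variables": t.selection.selected_indices.size,
            }
        )
    return pd.DataFrame(rows)


def choose_best_model(trained: dict[str, TrainedModel]) -> str:
    """Best model by highest Rp, then lowest RMSEP, then fewest variables."""
    def key(name: str):
        t = trained[name]
        return (
            -t.report.r_prediction,
            t.report.rmse_prediction,
            t.selection.selected_indices.size,
        )

    return min(trained, key=key)


def cmd_train(
    dataset: Dataset,
    selector_configs: dict[str, object],
    cv: CVConfig,
    out_dir: str | Path,
    split_ratio: float = 2 / 3,
    split_seed: int = 0,
) -> dict[str, object]:
    """Run all selectors, refit and evaluate, write the comparison table
    and per-algorithm model JSON; the best model becomes the warning model."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataset.split is None:
        dataset = split_calibration_prediction(dataset, split_ratio, split_seed)
    cal = dataset.rows("calibration")
    t0 = time.perf_counter()
    selections = run_all_selectors(
        dataset.features[cal], dataset.labels[cal], selector_configs, cv
    )
    trained: dict[str, TrainedModel] = {}
    for name, sel in selections.items():
        trained[name] = fit_selection_model(dataset, sel, cv)
        warn = _to_warning_model(trained[name], name)
        export_model(warn, out_dir / f"model_{name.lower()}.json")
    table = comparison_table(trained)
    table.to_csv(out_dir / "comparison.csv", index=False)
    best = choose_best_model(trained)
    export_model(_to_warning_model(trained[best], best), out_dir / "warning_model.json")
    logger.info(
        "trained %d selector models in %.1fs; best=%s-PLS (Rp=%.3f)",
        len(trained), time.perf_counter() - t0, best,
        trained[best].report.r_prediction,
    )
    return {"trained": trained, "table": table, "best": best, "out_dir": out_dir}


def _to_warning_model(trained: TrainedModel, name: str) -> WarningModel:
    return WarningModel(
        variable_indices=trained.selection.selected_indices,
        coefficients=trained.pls.coefficients,
        intercept=trained.pls.intercept,
        provenance=(
            f"{name}-PLS refit (seed {trained.selection.seed}, "
            f"{trained.pls.n_components} components)"
        ),
    )


def cmd_monitor(
    model: WarningModel, acquisition_paths: list[str | Path]
) -> list[MonitoringEntry]:
    """Score and grade each stored acquisition with a warning model."""
    entries = []
    for path in acquisition_paths:
        record = swio.read_acquisition_csv(path)
        x = flatten_record(record)
        y = score(model, x)
        label, in_range = grade(model, y)
        entries.append(
            MonitoringEntry(
                timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                warehouse_id=record.warehouse_id,
                day=record.day,
                channel_means={
                    ch.name: float(record.values[:, i].mean())
                    for i, ch in enumerate(CHANNELS)
                },
                score=y,
                grade=label,
                in_range=in_range,
            )
        )
    return entries


def monitoring_report_json(entries: list[MonitoringEntry]) -> str:
    return json.dumps(
        [
            {
                "timestamp": e.timestamp,
                "warehouse_id": e.warehouse_id,
                "day": e.day,
                "channel_means": e.channel_means,
                "score": e.score,
                "grade": e.grade,
                "in_range": e.in_range,
            }
            for e in entries
        ],
        indent=2,
    )


def monitoring_report_text(entries: list[MonitoringEntry]) -> str:
    lines = [f"{'warehouse':<10}{'day':>4}  {'Y':>9}  {'grade':<16}{'in range'}"]
    for e in entries:
        lines.append(
            f"{e.warehouse_id:<10}{e.day:>4}  {e.score:>9.3f}  "
            f"{e.grade:<16}{'yes' if e.in_range else 'NO'}"
        )
    return "\n".join(lines)


def cmd_report(run_dir: str | Path) -> str:
    """Aggregate a training run directory into one plain-text summary."""
    run_dir = Path(run_dir)
    comparison = run_dir / "comparison.csv"
    model_path = run_dir / "warning_model.json"
    missing = [p.name for p in (comparison, model_path) if not p.exists()]
    if missing:
        raise FileNotFoundError(
            f"{run_dir}: missing expected artifacts {missing}"
        )
    from .warning import import_model

    table = pd.read_csv(comparison)
    model = import_model(model_path)
    lines = ["Model comparison", "=" * 16, table.to_string(index=False), ""]
    lines += ["Selected variables by channel", "-" * 29]
    per_channel: dict[str, list[int]] = {}
    for idx in model.variable_indices:
        channel, _ = index_to_channel(int(idx))
        per_channel.setdefault(channel.name, []).append(int(idx))
    for ch in CHANNELS:
        if ch.name in per_channel:
            lines.append(f"{ch.name:<12} {per_channel[ch.name]}")
    lines += ["", "Warning model", "-" * 13, model.provenance, render_equation(model)]
    return "\n".join(lines) + "\n"
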