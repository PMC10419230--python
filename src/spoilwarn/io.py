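"""CSV and JSON readers/writers for acquisitions, datasets and ground truth.

Acquisition dialect: UTF-8 CSV, '.' decimal, metadata in '#'-prefixed
header lines (warehouse, day), then a header row naming each channel with
its unit, then one row per second.  Columns are matched by channel name,
not position, so a file with reordered columns still reads correctly.

Dataset dialect: one row per sample with columns
``sample_id, day, label, split, v0001..v3000`` (``v`` columns are the
1-based flattened variable numbers).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    CHANNELS,
    DAY_LABELS,
    N_TIMEPOINTS,
    AcquisitionRecord,
    Dataset,
)

_ACQ_FLOAT_FMT = "%.6f"


def write_acquisition_csv(record: AcquisitionRecord, path: str | Path) -> None:
    path = Path(path)
    header = ",".join(f"{ch.name} [{ch.unit}]" for ch in CHANNELS)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# warehouse_id: {record.warehouse_id}\n")
        fh.write(f"# day: {record.day}\n")
        fh.write(f"time_s,{header}\n")
        for t in range(N_TIMEPOINTS):
            row = ",".join(_ACQ_FLOAT_FMT % v for v in record.values[t])
            fh.write(f"{t},{row}\n")


def read_acquisition_csv(path: str | Path) -> AcquisitionRecord:
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    try:
        frame = pd.read_csv(_io.StringIO("".join(body_lines)))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed acquisition CSV ({exc})") from exc
    if "warehouse_id" not in meta or "day" not in meta:
        raise ValueError(f"{path}: missing '# warehouse_id' or '# day' metadata")
    if len(frame) != N_TIMEPOINTS:
        raise ValueError(
            f"{path}: acquisition must have {N_TIMEPOINTS} rows, found "
            f"{len(frame)}"
        )
    # columns matched by channel name (unit suffix optional), not position
    by_name = {}
    for col in frame.columns:
        name = col.split("[")[0].strip()
        by_name[name] = col
    columns = []
    for ch in CHANNELS:
        if ch.name not in by_name:
            raise ValueError(f"{path}: missing channel column {ch.name!r}")
        col = frame[by_name[ch.name]]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.isna().any():
            bad_row = int(numeric.index[numeric.isna()][0])
            raise ValueError(
                f"{path}: non-numeric value in column {ch.name!r}, row {bad_row}"
            )
        columns.append(numeric.to_numpy(dtype=float))
    values = np.column_stack(columns)
    return AcquisitionRecord(
        values=values, warehouse_id=meta["warehouse_id"], day=int(meta["day"])
    )


def _variable_columns(n_features: int) -> list[str]:
    width = max(4, len(str(n_features)))
    return [f"v{i:0{width}d}" for i in range(1, n_features + 1)]


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        dataset.features, columns=_variable_columns(dataset.n_features)
    )
    frame.insert(0, "sample_id", dataset.sample_ids)
    frame.insert(1, "day", dataset.days)
    frame.insert(2, "label", dataset.labels)
    split = dataset.split if dataset.split is not None else [""] * dataset.n_samples
    frame.insert(3, "split", split)
    frame.to_csv(path, index=False, float_format="%.10g")


def read_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    frame = pd.read_csv(path, keep_default_na=False)
    required = {"sample_id", "day", "label", "split"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ids = [str(s) for s in frame["sample_id"]]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    days = pd.to_numeric(frame["day"]).to_numpy()
    bad = [int(d) for d in days if int(d) not in DAY_LABELS]
    if bad:
        raise ValueError(f"{path}: day labels outside 1..8: {bad[:5]}")
    feature_cols = [c for c in frame.columns if c.startswith("v") and c[1:].isdigit()]
    feature_cols.sort(key=lambda c: int(c[1:]))
    features = frame[feature_cols].to_numpy(dtype=float)
    labels = pd.to_numeric(frame["label"]).to_numpy(dtype=float)
    split_raw = [str(s) for s in frame["split"]]
    split = None
    if any(split_raw):
        split = np.asarray(split_raw, dtype=object)
    return Dataset(
        features=features,
        days=days.astype(int),
        sample_ids=ids,
        labels=labels,
        split=split,
    )


def write_ground_truth_json(ground_truth, path: str | Path) -> None:
    """Serialize a GroundTruth sidecar (see :mod:`spoilwarn.simulate`)."""
    path = Path(path)
    doc = {
        "informative_indices": [int(i) for i in ground_truth.informative_indices],
        "coefficients": [float(c) for c in ground_truth.coefficients],
        "intercept": float(ground_truth.intercept),
        "day_of_sample": [int(d) for d in ground_truth.day_of_sample],
        "label_noise_sd": float(ground_truth.label_noise_sd),
        "seed": int(ground_truth.seed),
    }
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_ground_truth_json(path: str | Path):
    from .simulate import GroundTruth

    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        informative_indices=tuple(int(i) for i in doc["informative_indices"]),
        coefficients=tuple(float(c) for c in doc["coefficients"]),
        intercept=float(doc["intercept"]),
        day_of_sample=tuple(int(d) for d in doc["day_of_sample"]),
        label_noise_sd=float(doc["label_noise_sd"]),
        seed=int(doc["seed"]),
    )
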