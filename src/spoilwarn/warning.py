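"""Sparse linear early-warning models and spoilage grading.

A warning model scores a flattened acquisition x as

    Y = intercept + sum_j coef_j * x[index_j]

over a small set of characteristic variables, and maps Y onto ordered
spoilage grade bands: fresh (nominal Y 1-2), mild spoilage (3-4), medium
spoilage (5-6) and severe spoilage (7-8).  The published range leaves
gaps between bands, so classification uses midpoint boundaries (2.5, 4.5,
6.5) with the nominal ranges retained as metadata; scores outside the
operational range [1, 8] are clamped to the nearest band and flagged.

The published 20-variable SA-PLS reference model (two Temperature, two
Humidity, three CO2, six C2H4, four O2 and three VOC variables, intercept
38.9899) ships with the package and is returned verbatim by
:func:`paper_reference_model`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .chemometrics import CVConfig, fit_pls, kfold_rmsecv
from .data_model import Dataset, N_FEATURES
from .selection import SelectionResult

OPERATIONAL_RANGE = (1.0, 8.0)


@dataclass(frozen=True)
class GradeBand:
    """One labelled score interval [lower, upper)."""

    label: str
    lower: float
    upper: float
    nominal_range: tuple[float, float]

    def contains(self, y: float) -> bool:
        return self.lower <= y < self.upper


def default_grade_bands() -> tuple[GradeBand, ...]:
    return (
        GradeBand("fresh", -math.inf, 2.5, (1.0, 2.0)),
        GradeBand("mild spoilage", 2.5, 4.5, (3.0, 4.0)),
        GradeBand("medium spoilage", 4.5, 6.5, (5.0, 6.0)),
        GradeBand("severe spoilage", 6.5, math.inf, (7.0, 8.0)),
    )


@dataclass
class WarningModel:
    """Sparse linear early-warning model with grade bands."""

    variable_indices: np.ndarray
    coefficients: np.ndarray
    intercept: float
    grade_bands: tuple[GradeBand, ...] = field(default_factory=default_grade_bands)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.variable_indices = np.asarray(self.variable_indices, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.variable_indices.shape != self.coefficients.shape:
            raise ValueError(
                f"{self.variable_indices.size} indices but "
                f"{self.coefficients.size} coefficients"
            )
        if len(set(self.variable_indices.tolist())) != self.variable_indices.size:
            raise ValueError("variable indices must be distinct")
        if self.variable_indices.size and (
            self.variable_indices.min() < 1
            or self.variable_indices.max() > N_FEATURES
        ):
            raise ValueError(f"variable indices must lie in 1..{N_FEATURES}")
        lowers = [b.lower for b in self.grade_bands]
        if lowers != sorted(lowers):
            raise ValueError("grade bands must be ordered by score")

    @property
    def n_variables(self) -> int:
        return self.variable_indices.size


def score(model: WarningModel, x) -> float:
    """Evaluate the warning score Y on one flattened acquisition.

    ``x`` may be a full length-3000 vector or a mapping from variable
    number to value covering the model's indices.
    """
    if isinstance(x, dict):
        try:
            values = np.array([x[int(i)] for i in model.variable_indices], float)
        except KeyError as exc:
            raise KeyError(f"missing variable {exc.args[0]} in input mapping") from None
    else:
        x = np.asarray(x, dtype=float)
        if x.shape != (N_FEATURES,):
            raise ValueError(
                f"feature vector must have length {N_FEATURES}, got shape {x.shape}"
            )
        values = x[model.variable_indices - 1]
    return float(model.intercept + model.coefficients @ values)


def grade(model: WarningModel, y: float) -> tuple[str, bool]:
    """Map a score onto its spoilage grade.

    Returns (band label, in_range) where in_range is False when Y falls
    outside the operational score range [1, 8]; such scores are assigned
    the nearest band.
    """
    y = float(y)
    if not math.isfinite(y):
        raise ValueError(f"score must be finite, got {y}")
    in_range = OPERATIONAL_RANGE[0] <= y <= OPERATIONAL_RANGE[1]
    for band in model.grade_bands:
        if band.contains(y):
            return band.label, in_range
    return model.grade_bands[-1].label, in_range


def build_warning_model(
    dataset: Dataset,
    selection: SelectionResult,
    cv: CVConfig,
    max_components: int = 12,
    provenance: str | None = None,
) -> WarningModel:
    """Refit a sparse warning model on a selector's variables.

    Fits PLS on the calibration rows (all rows if the dataset is
    unsplit), with the component count chosen by RMSECV and capped at
    ``max_components``; coefficients are folded back to original sensor
    units.
    """
    if dataset.split is not None:
        mask = dataset.rows("calibration")
        if not mask.any():
            raise ValueError("dataset has no calibration rows")
    else:
        mask = np.ones(dataset.n_samples, dtype=bool)
    X = dataset.features[mask]
    y = dataset.labels[mask]
    indices = np.asarray(selection.selected_indices, dtype=int)
    if indices.max() > dataset.n_features:
        raise ValueError("selected index absent from dataset features")
    cv_eff = CVConfig(
        n_folds=cv.n_folds,
        shuffle_seed=cv.shuffle_seed,
        max_components=min(cv.max_components, max_components),
    )
    best_k = kfold_rmsecv(X, y, indices, cv_eff).best_n_components
    pls = fit_pls(X, y, best_k, feature_indices=indices)
    if provenance is None:
        provenance = (
            f"{selection.algorithm}-PLS refit "
            f"(seed {selection.seed}, {best_k} components)"
        )
    return WarningModel(
        variable_indices=indices,
        coefficients=pls.coefficients,
        intercept=pls.intercept,
        provenance=provenance,
    )


# ---------------------------------------------------------- serialization

def _model_from_document(doc: dict, origin: str) -> WarningModel:
    try:
        indices = doc["variable_indices"]
        coefficients = doc["coefficients"]
        intercept = float(doc["intercept"])
        bands_doc = doc["grade_bands"]
        provenance = doc.get("provenance", "")
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{origin}: malformed warning-model document ({exc})") from exc
    if len(indices) != len(coefficients):
        raise ValueError(
            f"{origin}: {len(indices)} indices but {len(coefficients)} coefficients"
        )
    bands = tuple(
        GradeBand(
            label=b["label"],
            lower=float(b["lower"]),
            upper=float(b["upper"]),
            nominal_range=tuple(b["nominal_range"]),
        )
        for b in bands_doc
    )
    return WarningModel(
        variable_indices=np.asarray(indices, dtype=int),
        coefficients=np.asarray(coefficients, dtype=float),
        intercept=intercept,
        grade_bands=bands,
        provenance=provenance,
    )


def paper_reference_model() -> WarningModel:
    """The bundled 20-variable published reference model, verbatim."""
    text = (
        resources.files("spoilwarn").joinpath("data/reference_model.json")
        .read_text(encoding="utf-8")
    )
    return _model_from_document(json.loads(text), "reference_model.json")


def export_model(model: WarningModel, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "schema_version": 1,
        "provenance": model.provenance,
        "variable_indices": [int(i) for i in model.variable_indices],
        "coefficients": [float(c) for c in model.coefficients],
        "intercept": float(model.intercept),
        "grade_bands": [
            {
                "label": b.label,
                "lower": b.lower,
                "upper": b.upper,
                "nominal_range": list(b.nominal_range),
            }
            for b in model.grade_bands
        ],
    }
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def import_model(path: str | Path) -> WarningModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: invalid JSON ({exc})") from exc
    return _model_from_document(doc, str(path))


def render_equation(model: WarningModel) -> str:
    """Human-readable equation: ``Y = 0.3264 X1 + ... + 38.9899``."""
    terms = []
    for rank, coef in enumerate(model.coefficients, start=1):
        sign = "-" if coef < 0 else "+"
        piece = f"{abs(coef):.4f} X{rank}"
        terms.append(piece if rank == 1 and coef >= 0 else f"{sign} {piece}")
    const = model.intercept
    terms.append(f"{'-' if const < 0 else '+'} {abs(const):.4f}")
    return "Y = " + " ".join(terms)
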