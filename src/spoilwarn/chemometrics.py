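"""PLS regression and the evaluation statistics shared by all selectors.

The regression engine is single-response PLS (PLS1) computed by NIPALS
with deflation.  Features and labels are autoscaled internally
(mean-centred, unit variance; constant columns get scale 1) because the
six sensor channels carry incommensurate units (ppm, %VOL, degC, %rh);
returned coefficients are folded back to the original scale so that
``predict(x) = intercept + coef . x``.

One NIPALS pass yields the coefficient path for every component count
1..K, so cross-validated RMSECV across component counts costs one fit per
fold.  Model quality is reported with the four conventional statistics:
Rc/RMSEC on the calibration set and Rp/RMSEP on the prediction set, plus
RMSECV (pooled out-of-fold RMSE) used as the selector fitness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Dataset

_EPS = 1e-12


@dataclass(frozen=True)
class CVConfig:
    """k-fold cross-validation settings shared by all selectors."""

    n_folds: int = 5
    shuffle_seed: int = 0
    max_components: int = 15

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.max_components < 1:
            raise ValueError("max_components must be at least 1")


@dataclass
class PLSModel:
    """A fitted PLS regression on a fixed variable subset.

    ``training_feature_indices`` are 1-based variable numbers into the
    matrix the model expects at prediction time; coefficients and
    intercept are on the original (unscaled) data scale.
    """

    n_components: int
    center_offsets: np.ndarray
    scale_factors: np.ndarray
    coefficients: np.ndarray
    intercept: float
    training_feature_indices: np.ndarray


@dataclass(frozen=True)
class EvaluationReport:
    """Rc/RMSEC (calibration) and Rp/RMSEP (prediction) of one model."""

    r_calibration: float
    rmse_calibration: float
    r_prediction: float
    rmse_prediction: float


@dataclass(frozen=True)
class RMSECVResult:
    """RMSECV per component count (index k-1 = k components) + the best."""

    values: np.ndarray
    best_n_components: int
    best_rmsecv: float


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd < _EPS, 1.0, sd)  # constant features: scale 1
    return (X - mean) / sd, mean, sd


def _coefficient_path(Xs: np.ndarray, ys: np.ndarray, max_components: int) -> np.ndarray:
    """NIPALS PLS1 on autoscaled data; column k-1 holds the k-component
    coefficient vector (scaled space).  Stops early when the residual
    covariance vanishes; remaining columns repeat the last valid one."""
    n, p = Xs.shape
    k_max = min(max_components, n - 1, p)
    Xd = Xs.copy()
    yd = ys.copy()
    weights: list[np.ndarray] = []
    loadings: list[np.ndarray] = []
    q: list[float] = []
    B = np.zeros((p, max(k_max, 1)))
    last = np.zeros(p)
    for k in range(k_max):
        w = Xd.T @ yd
        w_norm = np.linalg.norm(w)
        if w_norm < 1e-10:
            break
        w /= w_norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        pl = Xd.T @ t / tt
        qk = float(yd @ t / tt)
        Xd -= np.outer(t, pl)
        yd -= qk * t
        weights.append(w)
        loadings.append(pl)
        q.append(qk)
        W = np.column_stack(weights)
        P = np.column_stack(loadings)
        last = W @ np.linalg.solve(P.T @ W, np.asarray(q))
        B[:, k] = last
    for k in range(len(q), B.shape[1]):
        B[:, k] = last
    return B


def fit_pls(
    features: np.ndarray,
    labels: np.ndarray,
    n_components: int,
    feature_indices: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS1 model.

    ``feature_indices`` (1-based variable numbers) restricts the fit to a
    subset of the columns of ``features``; the model then expects a matrix
    of the same width at prediction time.  Without it, all columns are
    used and the indices default to 1..p.
    """
    X_full = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X_full.ndim != 2 or y.ndim != 1 or X_full.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, p) and labels length n")
    if feature_indices is None:
        indices = np.arange(1, X_full.shape[1] + 1)
    else:
        indices = np.asarray(feature_indices, dtype=int)
        if indices.size == 0:
            raise ValueError("feature subset must be non-empty")
        if indices.min() < 1 or indices.max() > X_full.shape[1]:
            raise ValueError("feature index outside matrix columns")
    X = X_full[:, indices - 1]
    n, p = X.shape
    if n < 2:
        raise ValueError("PLS needs at least 2 samples")
    if np.ptp(y) < _EPS:
        raise ValueError("labels are constant; nothing to regress")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must lie in 1..{min(n - 1, p)}, got {n_components}"
        )
    Xs, x_mean, x_sd = _autoscale(X)
    y_mean = y.mean()
    y_sd = y.std(ddof=0)
    ys = (y - y_mean) / y_sd
    B = _coefficient_path(Xs, ys, n_components)
    b_scaled = B[:, n_components - 1]
    coef = b_scaled * y_sd / x_sd
    intercept = float(y_mean - coef @ x_mean)
    return PLSModel(
        n_components=n_components,
        center_offsets=x_mean,
        scale_factors=x_sd,
        coefficients=coef,
        intercept=intercept,
        training_feature_indices=indices,
    )


def predict(model: PLSModel, features: np.ndarray) -> np.ndarray:
    """Predict labels; ``features`` must supply the model's variables."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] < model.training_feature_indices.max():
        raise ValueError(
            "feature matrix lacks the model's training variables "
            f"(needs at least {model.training_feature_indices.max()} columns)"
        )
    Xsub = X[:, model.training_feature_indices - 1]
    return model.intercept + Xsub @ model.coefficients


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation; errors on constant input."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if y_true.std() < _EPS or y_pred.std() < _EPS:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error with divisor n."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("inputs must have equal length")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def _fold_assignment(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} samples")
    order = np.random.default_rng(seed).permutation(n)
    return [fold for fold in np.array_split(order, n_folds)]


def kfold_rmsecv(
    features: np.ndarray,
    labels: np.ndarray,
    subset: np.ndarray,
    cv: CVConfig,
) -> RMSECVResult:
    """Seeded k-fold RMSECV over component counts 1..max_components.

    Out-of-fold predictions are pooled per component count, then RMSE is
    taken; the returned best component count minimizes RMSECV.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("variable subset must be non-empty")
    if subset.min() < 1 or subset.max() > X.shape[1]:
        raise ValueError("subset index outside matrix columns")
    Xsub = X[:, np.sort(subset) - 1]
    n, p = Xsub.shape
    folds = _fold_assignment(n, cv.n_folds, cv.shuffle_seed)
    k_cap = min(
        cv.max_components,
        p,
        min(n - len(fold) for fold in folds) - 1,
    )
    if k_cap < 1:
        raise ValueError("too few samples per fold for even one component")
    preds = np.zeros((n, k_cap))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        Xt, yt = Xsub[train], y[train]
        Xs, x_mean, x_sd = _autoscale(Xt)
        y_mean = yt.mean()
        y_sd = yt.std(ddof=0)
        if y_sd < _EPS:
            raise ValueError("constant labels within a training fold")
        B = _coefficient_path(Xs, (yt - y_mean) / y_sd, k_cap)
        Xe = (Xsub[fold] - x_mean) / x_sd
        preds[fold, :] = y_mean + (Xe @ B) * y_sd
    values = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    best = int(np.argmin(values))
    return RMSECVResult(
        values=values,
        best_n_components=best + 1,
        best_rmsecv=float(values[best]),
    )


def split_calibration_prediction(
    dataset: Dataset, ratio: float = 2 / 3, seed: int = 0
) -> Dataset:
    """Stratified-by-day random split into calibration/prediction sets.

    Each day stratum contributes ``round(ratio * n_day)`` samples to the
    calibration set (at least one to each side), so both sets span every
    acquisition day.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    split = np.asarray(["prediction"] * dataset.n_samples, dtype=object)
    for day in np.unique(dataset.days):
        rows = np.flatnonzero(dataset.days == day)
        if rows.size < 2:
            raise ValueError(
                f"day {day} has {rows.size} sample(s); need at least 2 to split"
            )
        n_cal = int(round(ratio * rows.size))
        n_cal = min(max(n_cal, 1), rows.size - 1)
        chosen = rng.permutation(rows)[:n_cal]
        split[chosen] = "calibration"
    return Dataset(
        features=dataset.features,
        days=dataset.days,
        sample_ids=list(dataset.sample_ids),
        labels=dataset.labels,
        split=split,
    )


def evaluate(model: PLSModel, dataset: Dataset) -> EvaluationReport:
    """Rc/RMSEC on calibration rows, Rp/RMSEP on prediction rows."""
    cal = dataset.rows("calibration")
    pred = dataset.rows("prediction")
    if not cal.any() or not pred.any():
        raise ValueError("both calibration and prediction splits must be non-empty")
    y_cal_hat = predict(model, dataset.features[cal])
    y_pred_hat = predict(model, dataset.features[pred])
    return EvaluationReport(
        r_calibration=pearson_r(dataset.labels[cal], y_cal_hat),
        rmse_calibration=rmse(dataset.labels[cal], y_cal_hat),
        r_prediction=pearson_r(dataset.labels[pred], y_pred_hat),
        rmse_prediction=rmse(dataset.labels[pred], y_pred_hat),
    )
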