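"""PLS regression of log10(IC50), cross-validation, component sweep, and benchmark.

The model is single-response partial least squares on centred (not scaled)
features: latent components maximize covariance between projected features
and the response, and prediction is ``(x - x_mean) @ beta + y_mean``.
Evaluation is k-fold cross-validation (default k=5) with per-fold R² and
RMSE averaged across folds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    RandomForestRegressor,
)
from sklearn.svm import SVR

__all__ = [
    "PLSModel",
    "CVReport",
    "SweepTable",
    "BenchmarkTable",
    "fit_pls",
    "predict",
    "r_squared",
    "rmse",
    "make_folds",
    "cross_validate",
    "component_sweep",
    "benchmark",
    "BENCHMARK_ALGORITHMS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PLSModel:
    """A fitted single-response PLS model."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # p x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A-vector
    coef: np.ndarray  # p-vector

    @property
    def p(self) -> int:
        return self.x_mean.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"expected {self.p} features, got {X.shape[1]}")
        return (X - self.x_mean) @ self.coef + self.y_mean

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PLSModel":
        return cls(
            n_components=int(payload["n_components"]),
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            y_mean=float(payload["y_mean"]),
            x_weights=np.asarray(payload["x_weights"], dtype=float),
            x_loadings=np.asarray(payload["x_loadings"], dtype=float),
            y_loadings=np.asarray(payload["y_loadings"], dtype=float),
            coef=np.asarray(payload["coef"], dtype=float),
        )


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int = 3) -> PLSModel:
    """Fit single-response PLS (NIPALS with X-deflation, centred, unscaled)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y length mismatch")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: y has zero variance")
    if not 1 <= n_components <= min(p, n - 1):
        raise ValueError(
            f"n_components={n_components} outside valid range 1..{min(p, n - 1)}"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return PLSModel(
        n_components=n_components,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        x_weights=pls.x_weights_.copy(),
        x_loadings=pls.x_loadings_.copy(),
        y_loadings=pls.y_loadings_.ravel().copy(),
        coef=pls.coef_.ravel().copy(),
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def r_squared(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.size != y_pred.size or y.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined: y has zero variance")
    return float(1.0 - np.sum((y - y_pred) ** 2) / ss_tot)


def rmse(y: np.ndarray, y_pred: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.size != y_pred.size or y.size == 0:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


@dataclass(frozen=True)
class CVReport:
    """Per-fold and mean held-out metrics of one cross-validation run."""

    k: int
    seed: int
    per_fold: tuple[tuple[float, float], ...]  # (r2, rmse) per fold
    mean_r2: float
    mean_rmse: float

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "per_fold": [{"r2": r, "rmse": e} for r, e in self.per_fold],
            "mean_r2": self.mean_r2,
            "mean_rmse": self.mean_rmse,
        }


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffle indices with ``seed`` and split into k near-equal folds."""
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must satisfy 2 <= k <= n={n}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return [fold for fold in np.array_split(idx, k)]


def _default_factory(X, y):
    return fit_pls(X, y, n_components=3)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    model_factory=None,
    seed: int = 0,
    return_predictions: bool = False,
):
    """k-fold cross-validation with per-fold metrics averaged across folds.

    ``model_factory(X_train, y_train)`` must return an object with a
    ``predict`` method; the default fits PLS with 3 components.  With
    ``return_predictions`` a second value is returned: an (n, 2) array of
    (out-of-fold prediction, fold index) aligned with sample order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    factory = model_factory or _default_factory
    folds = make_folds(len(y), k, seed)
    per_fold = []
    oof = np.full((len(y), 2), np.nan)
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        model = factory(X[train_idx], y[train_idx])
        y_hat = np.asarray(model.predict(X[test_idx]), dtype=float).ravel()
        per_fold.append((r_squared(y[test_idx], y_hat), rmse(y[test_idx], y_hat)))
        oof[test_idx, 0] = y_hat
        oof[test_idx, 1] = fold_id
    report = CVReport(
        k=k,
        seed=seed,
        per_fold=tuple(per_fold),
        mean_r2=float(np.mean([r for r, _ in per_fold])),
        mean_rmse=float(np.mean([e for _, e in per_fold])),
    )
    if return_predictions:
        return report, oof
    return report


@dataclass(frozen=True)
class SweepTable:
    """Cross-validated performance per PLS component count."""

    rows: tuple[tuple[int, float, float], ...]  # (A, cv_r2, cv_rmse)
    selected_A: int

    def to_dict(self) -> dict:
        return {
            "rows": [
                {"components": a, "cv_r2": r, "cv_rmse": e} for a, r, e in self.rows
            ],
            "selected_components": self.selected_A,
        }


def component_sweep(
    X: np.ndarray,
    y: np.ndarray,
    A_range=range(2, 11),
    k: int = 5,
    seed: int = 0,
) -> SweepTable:
    """Cross-validate PLS for each component count; select the argmax mean R².

    All component counts are evaluated on identical folds; ties break toward
    the smaller count.
    """
    rows = []
    for A in A_range:
        rep = cross_validate(
            X, y, k=k, seed=seed,
            model_factory=lambda Xt, yt, A=A: fit_pls(Xt, yt, n_components=A),
        )
        rows.append((int(A), rep.mean_r2, rep.mean_rmse))
    best = max(rows, key=lambda row: (row[1], -row[0]))
    return SweepTable(rows=tuple(rows), selected_A=best[0])


def _comparator_factories(seed: int):
    # library defaults; tree/boosting seeds derived from the CV seed
    return {
        "PLS (3 components)": lambda X, y: fit_pls(X, y, n_components=3),
        "SVR": lambda X, y: SVR().fit(X, y),
        "Random Forest": lambda X, y: RandomForestRegressor(random_state=seed).fit(X, y),
        "Extra Trees": lambda X, y: ExtraTreesRegressor(random_state=seed).fit(X, y),
        "AdaBoost": lambda X, y: AdaBoostRegressor(random_state=seed).fit(X, y),
    }


BENCHMARK_ALGORITHMS = tuple(_comparator_factories(0))


@dataclass(frozen=True)
class BenchmarkTable:
    """Cross-validated R²/RMSE per algorithm, identical folds, sorted by R² descending."""

    rows: tuple[tuple[str, float, float], ...]  # (name, r2, rmse); nan = failed

    def to_dict(self) -> dict:
        return {
            "rows": [{"algorithm": a, "cv_r2": r, "cv_rmse": e} for a, r, e in self.rows]
        }


def benchmark(X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0) -> BenchmarkTable:
    """Evaluate PLS and the comparator regressors on identical CV folds."""
    rows = []
    for name, factory in _comparator_factories(seed).items():
        try:
            rep = cross_validate(X, y, k=k, seed=seed, model_factory=factory)
            rows.append((name, rep.mean_r2, rep.mean_rmse))
        except Exception as exc:  # a failed algorithm must not sink the table
            logger.warning("benchmark algorithm %s failed: %s", name, exc)
            rows.append((name, float("nan"), float("nan")))
    rows.sort(key=lambda row: (-(row[1] if np.isfinite(row[1]) else -np.inf), row[0]))
    return BenchmarkTable(rows=tuple(rows))


def save_model(path, model: PLSModel, config: dict | None = None,
               data_hash: str | None = None) -> None:
    """Persist a PLS model as structured JSON with config and data hash."""
    payload = {"model": model.to_dict(), "config": config or {}, "data_hash": data_hash}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PLSModel:
    with open(path) as fh:
        payload = json.load(fh)
    return PLSModel.from_dict(payload["model"])


def array_hash(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()[:16]
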