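"""Single-time-point body-weight prediction under calf-grouped cross-validation.

Body weight (lb) is predicted from age plus the five image-derived body
metrics with (a) ordinary least squares and (b) gradient-boosted trees
tuned by randomized search. Validation is grouped at the animal: calves —
never rows — are partitioned into 5 folds, so no calf contributes images
to both train and test, and the whole procedure is repeated with fresh
random fold assignments to measure the spread of each accuracy metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from xgboost import XGBRegressor

from ._stats import compare_groups
from .depth_io import ValidationError

__all__ = [
    "FeatureSpec",
    "SearchSpace",
    "grouped_kfold",
    "regression_metrics",
    "fit_linear",
    "fit_gbt",
    "repeat_cv",
    "METRIC_NAMES",
]

METRIC_NAMES = ("r2", "mse", "rmse", "mae", "mape")


@dataclass(frozen=True)
class FeatureSpec:
    """Predictors (age + the five body metrics) and response for BW models."""

    predictors: tuple[str, ...] = (
        "age_days",
        "length_px",
        "width_px",
        "avg_height_mm",
        "volume_mm_px2",
        "contour_area_px2",
    )
    response: str = "bw_lb"

    def validate(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = [*self.predictors, self.response]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValidationError(f"table missing model columns: {missing}")
        if table[cols].isna().any().any():
            raise ValidationError("missing values in modeling columns")
        return table

    def design(self, table: pd.DataFrame) -> np.ndarray:
        return table[list(self.predictors)].to_numpy(dtype=float)


@dataclass(frozen=True)
class SearchSpace:
    """Randomized-search space for the gradient-boosted trees.

    The canonical space samples the learning rate in [0.01, 0.9], the
    number of estimators in [50, 10000] and both regularization terms in
    [0, 1], with 1000 sampled configurations. The package default is the
    desk profile — the same ranges but 50 iterations and at most 500
    estimators — which the analyses use; :meth:`full` restores the
    canonical configuration.
    """

    learning_rate: tuple[float, float] = (0.01, 0.9)
    n_estimators: tuple[int, int] = (50, 500)
    reg_alpha: tuple[float, float] = (0.0, 1.0)
    reg_lambda: tuple[float, float] = (0.0, 1.0)
    n_iterations: int = 50

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")

    @classmethod
    def full(cls) -> "SearchSpace":
        return cls(n_estimators=(50, 10_000), n_iterations=1000)

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "learning_rate": float(rng.uniform(*self.learning_rate)),
            "n_estimators": int(rng.integers(self.n_estimators[0], self.n_estimators[1] + 1)),
            "reg_alpha": float(rng.uniform(*self.reg_alpha)),
            "reg_lambda": float(rng.uniform(*self.reg_lambda)),
        }


def grouped_kfold(
    calf_ids: Sequence[str], k: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """Partition calves (not rows) into k folds; returns (train, test) calf lists.

    Folds are as even as possible, disjoint, and cover every calf; with 20
    calves and k=5 each test fold holds 4 calves and each training set 16.
    """
    calves = sorted(set(map(str, calf_ids)))
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(calves):
        raise ValidationError(f"k={k} exceeds number of calves ({len(calves)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(calves))
    folds = [sorted(np.asarray(calves)[order[i::k]].tolist()) for i in range(k)]
    out = []
    for i in range(k):
        test = folds[i]
        train = sorted(c for j, f in enumerate(folds) if j != i for c in f)
        out.append((train, test))
    return out


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """R^2, MSE, RMSE, MAE and MAPE (%) of predictions against truth.

    R^2 uses the mean of ``y`` itself as the baseline (the test-set mean
    when scoring held-out predictions). MAPE requires strictly positive
    responses.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValidationError("y and yhat must be equal-length vectors of length >= 2")
    if np.any(y == 0):
        raise ValidationError("MAPE undefined: zero response value")
    resid = y - yhat
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return {
        "r2": 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan"),
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mae": float(np.mean(np.abs(resid))),
        "mape": float(100.0 * np.mean(np.abs(resid) / np.abs(y))),
    }


def fit_linear(
    train: pd.DataFrame, spec: FeatureSpec | None = None
) -> Callable[[pd.DataFrame], np.ndarray]:
    """Ordinary least squares on the six predictors plus intercept."""
    spec = spec or FeatureSpec()
    spec.validate(train)
    X = spec.design(train)
    y = train[spec.response].to_numpy(dtype=float)
    if len(train) < X.shape[1] + 2:
        raise ValidationError("too few rows for OLS")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValidationError("rank-deficient design matrix")
    model = LinearRegression().fit(X, y)

    def predict(table: pd.DataFrame) -> np.ndarray:
        return model.predict(spec.design(table))

    predict.model = model  # type: ignore[attr-defined]
    return predict


def _xgb(config: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        **config,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )


def fit_gbt(
    train: pd.DataFrame,
    spec: FeatureSpec | None = None,
    space: SearchSpace | None = None,
    seed: int = 0,
) -> Callable[[pd.DataFrame], np.ndarray]:
    """Gradient-boosted trees with randomized hyperparameter search.

    Samples ``space.n_iterations`` configurations uniformly, scores each by
    3-fold CV RMSE within the training split (so the outer test data never
    leaks into model selection), then refits the best configuration on the
    full training split. Deterministic for a fixed seed.
    """
    spec = spec or FeatureSpec()
    space = space or SearchSpace()
    spec.validate(train)
    if len(train) < 10:
        raise ValidationError("need at least 10 training rows")
    y = train[spec.response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("degenerate training target (constant)")
    X = spec.design(train)

    rng = np.random.default_rng(seed)
    inner = np.arange(len(train)) % 3  # deterministic 3-fold assignment
    best_rmse, best_config = np.inf, None
    for _ in range(space.n_iterations):
        config = space.sample(rng)
        sq_errs = []
        for fold in range(3):
            tr, te = inner != fold, inner == fold
            model = _xgb(config, seed).fit(X[tr], y[tr])
            sq_errs.append((model.predict(X[te]) - y[te]) ** 2)
        rmse = float(np.sqrt(np.mean(np.concatenate(sq_errs))))
        if rmse < best_rmse:
            best_rmse, best_config = rmse, config

    final = _xgb(best_config, seed).fit(X, y)

    def predict(table: pd.DataFrame) -> np.ndarray:
        return final.predict(spec.design(table))

    predict.model = final  # type: ignore[attr-defined]
    predict.config = best_config  # type: ignore[attr-defined]
    return predict


DEFAULT_MODELS: dict[str, Callable] = {
    "linear": lambda train, spec, seed: fit_linear(train, spec),
    "gbt": lambda train, spec, seed: fit_gbt(train, spec, seed=seed),
}


def repeat_cv(
    table: pd.DataFrame,
    models: dict[str, Callable] | None = None,
    k: int = 5,
    n_rep: int = 100,
    seed: int = 0,
    spec: FeatureSpec | None = None,
) -> dict:
    """Repeated calf-grouped k-fold CV; one pooled metric set per repetition.

    Each repetition reshuffles calves into folds, fits every model on each
    training fold and predicts its test fold; test predictions are pooled
    over the k folds before computing metrics, giving one value per metric
    per repetition. Model factories take ``(train, spec, seed)`` and return
    a predictor. Reports per-repetition metrics, mean +/- SD, and a
    one-way ANOVA between models per metric.
    """
    spec = spec or FeatureSpec()
    models = models or DEFAULT_MODELS
    spec.validate(table)
    rows = []
    for rep in range(n_rep):
        rep_seed = seed * 100_003 % (2**31 - 1) + rep
        folds = grouped_kfold(table["calf_id"], k=k, seed=rep_seed)
        preds: dict[str, list[np.ndarray]] = {m: [] for m in models}
        truths: list[np.ndarray] = []
        for train_calves, test_calves in folds:
            assert not set(train_calves) & set(test_calves)
            train = table[table["calf_id"].isin(train_calves)]
            test = table[table["calf_id"].isin(test_calves)]
            truths.append(test[spec.response].to_numpy(dtype=float))
            for name, factory in models.items():
                predictor = factory(train, spec, rep_seed)
                preds[name].append(np.asarray(predictor(test), dtype=float))
        y = np.concatenate(truths)
        for name in models:
            m = regression_metrics(y, np.concatenate(preds[name]))
            rows.append({"rep": rep, "model": name, **m})
    per_rep = pd.DataFrame(rows)

    report: dict = {"per_repetition": per_rep, "metrics": {}}
    for metric in METRIC_NAMES:
        groups = {m: g[metric].to_numpy() for m, g in per_rep.groupby("model")}
        report["metrics"][metric] = compare_groups(groups, family_size=1)
    return report
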