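"""Time-forward body-weight forecasting with a random-intercept mixed model.

Longitudinal evaluation splits each calf's visit history chronologically:
the earliest X% of observations train the models, the remainder — always
strictly later in age — is forecast. Candidate models are ordinary least
squares, gradient-boosted trees, and a linear mixed model with the same
six fixed effects (age + five body metrics) plus a per-calf random
intercept, fitted by REML. Because a longitudinal analysis is inherently
run once, variability is manufactured by repeating the whole procedure
with one randomly deleted (calf, time point) observation per iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._stats import compare_groups
from .bw_predict import (
    FeatureSpec,
    METRIC_NAMES,
    SearchSpace,
    fit_gbt,
    fit_linear,
    regression_metrics,
)
from .depth_io import ValidationError

__all__ = [
    "SplitSpec",
    "MixedModelFit",
    "time_forward_split",
    "drop_random_timepoint",
    "fit_lmm",
    "run_forecast",
    "DEFAULT_SPLITS",
]

DEFAULT_SPLITS = (0.9, 0.8, 0.7, 0.6, 0.5)


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train fraction plus the minimum usable visit count."""

    train_fraction: float = 0.9
    min_obs_per_calf: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")


def time_forward_split(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-calf chronological split: earliest floor(X% * n) visits train.

    The train count is clamped to [1, n-1] so every retained calf appears
    on both sides, and for every calf max(train ages) < min(test ages).
    Calves with fewer than ``min_obs_per_calf`` observations are dropped
    with a warning (sparse histories cannot support forecasting).
    """
    train_parts, test_parts = [], []
    for calf, g in table.groupby("calf_id"):
        g = g.sort_values("age_days", kind="stable")
        n = len(g)
        if n < spec.min_obs_per_calf:
            warnings.warn(
                f"calf {calf!r} has only {n} observations; dropped from the split",
                stacklevel=2,
            )
            continue
        n_train = int(np.clip(np.floor(spec.train_fraction * n), 1, n - 1))
        train_parts.append(g.iloc[:n_train])
        test_parts.append(g.iloc[n_train:])
    if not train_parts:
        raise ValidationError("no calf has enough observations to split")
    return (
        pd.concat(train_parts).reset_index(drop=True),
        pd.concat(test_parts).reset_index(drop=True),
    )


def drop_random_timepoint(
    table: pd.DataFrame, seed: int, min_obs_per_calf: int = 5
) -> pd.DataFrame:
    """Remove exactly one (calf, time point) row uniformly at random.

    Emulates a missed farm visit. Only calves that would keep at least
    ``min_obs_per_calf`` observations are eligible donors. Deterministic
    per seed.
    """
    counts = table.groupby("calf_id")["age_days"].size()
    eligible = counts[counts >= min_obs_per_calf + 1].index
    pool = table.index[table["calf_id"].isin(eligible)]
    if len(pool) == 0:
        raise ValidationError("no calf has enough observations to lose one")
    rng = np.random.default_rng(seed)
    drop_idx = rng.choice(pool.to_numpy())
    return table.drop(index=drop_idx).reset_index(drop=True)


@dataclass
class MixedModelFit:
    """REML random-intercept fit: fixed coefficients + variance components."""

    fixed_effects: dict[str, float]
    random_intercept_var: float
    residual_var: float
    random_intercepts: dict[str, float]
    converged: bool
    spec: FeatureSpec

    def predict(self, table: pd.DataFrame, use_random_effects: bool = True) -> np.ndarray:
        """Predict BW; training calves get their predicted random intercept.

        Calves never seen in training (or with ``use_random_effects=False``)
        are predicted from the fixed effects alone.
        """
        X = table[list(self.spec.predictors)].to_numpy(dtype=float)
        beta = np.array([self.fixed_effects[p] for p in self.spec.predictors])
        yhat = self.fixed_effects["intercept"] + X @ beta
        if use_random_effects:
            offsets = table["calf_id"].map(self.random_intercepts).fillna(0.0).to_numpy()
            yhat = yhat + offsets
        return yhat

    def __call__(self, table: pd.DataFrame) -> np.ndarray:
        return self.predict(table)


def fit_lmm(train: pd.DataFrame, spec: FeatureSpec | None = None) -> MixedModelFit:
    """Fit BW on the six fixed effects with a per-calf random intercept (REML).

    A singular fit (between-calf variance estimated at the boundary) is
    flagged with a warning and reported as variance 0 rather than raised.
    """
    spec = spec or FeatureSpec()
    spec.validate(train)
    if train["calf_id"].nunique() < 2:
        raise ValidationError("need at least 2 calves for a mixed model")
    if (train.groupby("calf_id").size() < 2).any():
        raise ValidationError("every calf needs at least 2 observations")
    X = sm.add_constant(train[list(spec.predictors)].to_numpy(dtype=float))
    y = train[spec.response].to_numpy(dtype=float)
    groups = train["calf_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits warn; handled below
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    names = ["intercept", *spec.predictors]
    fixed = {n: float(b) for n, b in zip(names, res.fe_params)}
    re_var = float(np.asarray(res.cov_re).squeeze())
    if re_var <= 1e-10 or not res.converged:
        if re_var <= 1e-10:
            warnings.warn("singular fit: random-intercept variance at 0", stacklevel=2)
        re_var = max(re_var, 0.0)
    rand = {str(k): float(np.asarray(v).squeeze()) for k, v in res.random_effects.items()}
    return MixedModelFit(
        fixed_effects=fixed,
        random_intercept_var=re_var,
        residual_var=float(res.scale),
        random_intercepts=rand,
        converged=bool(res.converged),
        spec=spec,
    )


def _default_forecast_models(space: SearchSpace | None) -> dict[str, Callable]:
    space = space or SearchSpace()
    return {
        "linear": lambda train, spec, seed: fit_linear(train, spec),
        "gbt": lambda train, spec, seed: fit_gbt(train, spec, space=space, seed=seed),
        "lmm": lambda train, spec, seed: fit_lmm(train, spec),
    }


def run_forecast(
    table: pd.DataFrame,
    models: dict[str, Callable] | None = None,
    splits: tuple[float, ...] = DEFAULT_SPLITS,
    n_iter: int = 100,
    seed: int = 0,
    spec: FeatureSpec | None = None,
    min_obs_per_calf: int = 5,
    search_space: SearchSpace | None = None,
    family_size: int = 3,
) -> dict:
    """Repeated time-forward forecasting across train:test splits.

    Per iteration: delete one random (calf, time) observation, split each
    calf's history chronologically, fit every model on the train side and
    score it on the strictly later test side. Per split: mean +/- SD per
    model per metric, one-way ANOVA with Bonferroni adjustment
    (``family_size`` defaults to the three-model comparison) plus Tukey
    letters and eta^2. Iteration seeds derive from the master seed by
    counter, so a run is exactly reproducible.
    """
    spec = spec or FeatureSpec()
    models = models or _default_forecast_models(search_space)
    spec.validate(table)
    report: dict = {"splits": {}}
    for frac in splits:
        split_spec = SplitSpec(train_fraction=frac, min_obs_per_calf=min_obs_per_calf)
        rows = []
        for it in range(n_iter):
            it_seed = (seed * 100_003 + int(frac * 100) * 1_009 + it) % (2**31 - 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reduced = drop_random_timepoint(table, it_seed, min_obs_per_calf)
                train, test = time_forward_split(reduced, split_spec)
            # temporal integrity: no test row precedes any training row of its calf
            max_train = train.groupby("calf_id")["age_days"].max()
            min_test = test.groupby("calf_id")["age_days"].min()
            assert (max_train[min_test.index] < min_test).all()
            y = test[spec.response].to_numpy(dtype=float)
            for name, factory in models.items():
                predictor = factory(train, spec, it_seed)
                m = regression_metrics(y, np.asarray(predictor(test), dtype=float))
                rows.append({"iteration": it, "model": name, **m})
        per_iter = pd.DataFrame(rows)
        split_report: dict = {"per_iteration": per_iter, "metrics": {}}
        for metric in METRIC_NAMES:
            groups = {m: g[metric].to_numpy() for m, g in per_iter.groupby("model")}
            split_report["metrics"][metric] = compare_groups(groups, family_size=family_size)
        label = f"{int(frac * 100)}:{int(round((1 - frac) * 100))}"
        report["splits"][label] = split_report
    return report
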