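"""Time-forward splitting, missing-visit simulation, and the mixed model."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from calfdepth.bw_longitudinal import (
    MixedModelFit,
    SplitSpec,
    drop_random_timepoint,
    fit_lmm,
    run_forecast,
    time_forward_split,
)
from calfdepth.bw_predict import FeatureSpec, fit_linear
from calfdepth.depth_io import ValidationError
from calfdepth.synthetic_data import simulate_growth, simulate_lmm_herd


def herd_with_visits(visits_by_calf):
    rows = []
    for calf, n in visits_by_calf.items():
        for j in range(n):
            rows.append(
                {
                    "calf_id": calf,
                    "date": f"d{j}",
                    "age_days": 21 + 3 * j,
                    "bw_lb": 100.0 + 1.5 * j,
                }
            )
    return pd.DataFrame(rows)


class TestTimeForwardSplit:
    def test_ninety_ten_on_ten_visits(self):
        t = herd_with_visits({"c1": 10})
        train, test = time_forward_split(t, SplitSpec(0.9))
        assert (len(train), len(test)) == (9, 1)

    def test_fifty_fifty_on_nine_visits_floors(self):
        t = herd_with_visits({"c1": 9})
        train, test = time_forward_split(t, SplitSpec(0.5))
        assert (len(train), len(test)) == (4, 5)

    def test_sparse_calf_dropped_with_warning(self):
        t = herd_with_visits({"c1": 4, "c2": 10})
        with pytest.warns(UserWarning, match="c1"):
            train, test = time_forward_split(t, SplitSpec(0.9, min_obs_per_calf=5))
        assert set(train.calf_id) == {"c2"}

    def test_every_calf_has_later_test_ages(self, herd):
        for frac in (0.9, 0.8, 0.7, 0.6, 0.5):
            train, test = time_forward_split(herd, SplitSpec(frac))
            max_train = train.groupby("calf_id")["age_days"].max()
            min_test = test.groupby("calf_id")["age_days"].min()
            assert (max_train[min_test.index] < min_test).all()

    def test_no_usable_calf_rejected(self):
        t = herd_with_visits({"c1": 2})
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning):
                time_forward_split(t, SplitSpec(0.9, min_obs_per_calf=5))


class TestDropRandomTimepoint:
    def test_removes_exactly_one_row(self, herd):
        out = drop_random_timepoint(herd, seed=0)
        assert len(out) == len(herd) - 1

    def test_deterministic_per_seed(self, herd):
        o1 = drop_random_timepoint(herd, seed=42)
        o2 = drop_random_timepoint(herd, seed=42)
        assert o1.equals(o2)

    def test_removal_approximately_uniform_over_rows(self):
        t = herd_with_visits({"c1": 8, "c2": 8, "c3": 8})
        t = t.reset_index(drop=True)
        counts = np.zeros(len(t))
        n_draws = 2000
        for seed in range(n_draws):
            kept = drop_random_timepoint(t, seed=seed, min_obs_per_calf=5)
            missing = set(zip(t.calf_id, t.age_days)) - set(zip(kept.calf_id, kept.age_days))
            (row,) = missing
            idx = t.index[(t.calf_id == row[0]) & (t.age_days == row[1])][0]
            counts[idx] += 1
        chi2 = ((counts - n_draws / len(t)) ** 2 / (n_draws / len(t))).sum()
        assert stats.chi2.sf(chi2, df=len(t) - 1) > 0.001

    def test_protects_minimum_history(self):
        t = herd_with_visits({"c1": 5, "c2": 6})
        for seed in range(50):
            kept = drop_random_timepoint(t, seed=seed, min_obs_per_calf=5)
            assert (kept.groupby("calf_id").size() >= 5).all()

    def test_no_eligible_calf_rejected(self):
        t = herd_with_visits({"c1": 5})
        with pytest.raises(ValidationError):
            drop_random_timepoint(t, seed=0, min_obs_per_calf=5)


class TestFitLmm:
    def test_zero_between_calf_variance_detected(self, rng):
        spec = FeatureSpec()
        X = rng.uniform(0, 10, size=(60, 6))
        y = 5.0 + X @ np.arange(1.0, 7.0) + rng.normal(0, 1.0, 60)
        t = pd.DataFrame(X, columns=spec.predictors).assign(
            bw_lb=y, calf_id=np.repeat([f"c{i}" for i in range(10)], 6)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # boundary fits may flag
            fit = fit_lmm(t, spec)
        assert fit.random_intercept_var == pytest.approx(0.0, abs=0.5)

    def test_parameter_recovery_on_known_herd(self):
        table, truth = simulate_lmm_herd(n_calves=50, visits_per_calf=10, seed=3)
        fit = fit_lmm(table)
        assert fit.fixed_effects["age_days"] == pytest.approx(
            truth["beta"]["age_days"], rel=0.10
        )
        assert fit.random_intercept_var == pytest.approx(truth["sigma_b"] ** 2, rel=0.5)
        assert fit.residual_var == pytest.approx(truth["sigma_e"] ** 2, rel=0.3)

    def test_training_calves_use_their_random_intercept(self):
        table, _ = simulate_lmm_herd(n_calves=10, visits_per_calf=8, sigma_b=15, seed=1)
        fit = fit_lmm(table)
        with_re = fit.predict(table, use_random_effects=True)
        without = fit.predict(table, use_random_effects=False)
        assert not np.allclose(with_re, without)
        # the random effects must help on the training calves
        y = table.bw_lb.to_numpy()
        assert np.mean((y - with_re) ** 2) < np.mean((y - without) ** 2)

    def test_matches_ols_when_no_calf_structure(self, rng):
        # with no between-calf variance the REML fixed effects collapse to OLS
        spec = FeatureSpec()
        X = rng.uniform(0, 10, size=(80, 6))
        y = 5.0 + X @ np.arange(1.0, 7.0) + rng.normal(0, 1.0, 80)
        t = pd.DataFrame(X, columns=spec.predictors).assign(
            bw_lb=y, calf_id=np.repeat([f"c{i}" for i in range(10)], 8)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            lmm = fit_lmm(t, spec)
        ols = fit_linear(t, spec)
        np.testing.assert_allclose(
            [lmm.fixed_effects[p] for p in spec.predictors], ols.model.coef_, atol=0.05
        )

    def test_too_few_calves_rejected(self):
        t = herd_with_visits({"c1": 6}).assign(
            **{c: 1.0 for c in FeatureSpec().predictors if c != "age_days"}
        )
        with pytest.raises(ValidationError):
            fit_lmm(t)


class TestRunForecast:
    def test_identical_models_show_no_effect(self, herd):
        factory = lambda tr, sp, sd: fit_linear(tr, sp)  # noqa: E731
        rep = run_forecast(
            herd,
            models={"m1": factory, "m2": factory, "m3": factory},
            splits=(0.5,),
            n_iter=3,
            seed=0,
        )
        r = rep["splits"]["50:50"]["metrics"]["r2"]
        assert r["eta_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_smaller_train_fraction_shrinks_training_set(self, herd):
        sizes = []
        for frac in (0.9, 0.7, 0.5):
            train, _ = time_forward_split(herd, SplitSpec(frac))
            sizes.append(len(train))
        assert sizes == sorted(sizes, reverse=True)

    def test_split_labels_and_reproducibility(self, herd):
        factory = lambda tr, sp, sd: fit_linear(tr, sp)  # noqa: E731
        r1 = run_forecast(herd, models={"linear": factory}, splits=(0.9, 0.5), n_iter=2, seed=3)
        r2 = run_forecast(herd, models={"linear": factory}, splits=(0.9, 0.5), n_iter=2, seed=3)
        assert set(r1["splits"]) == {"90:10", "50:50"}
        pd.testing.assert_frame_equal(
            r1["splits"]["50:50"]["per_iteration"], r2["splits"]["50:50"]["per_iteration"]
        )

    def test_mixed_model_beats_pooled_ols_on_heterogeneous_herd(self):
        from calfdepth.synthetic_data import GrowthModelParams

        t = simulate_growth(GrowthModelParams.heterogeneous(), seed=5)
        rep = run_forecast(
            t,
            models={
                "linear": lambda tr, sp, sd: fit_linear(tr, sp),
                "lmm": lambda tr, sp, sd: fit_lmm(tr, sp),
            },
            splits=(0.5,),
            n_iter=5,
            seed=1,
        )
        means = rep["splits"]["50:50"]["metrics"]["r2"]["means"]
        assert means["lmm"] > means["linear"]


class TestMixedModelFitPredict:
    def test_unseen_calf_falls_back_to_fixed_effects(self):
        table, _ = simulate_lmm_herd(n_calves=6, visits_per_calf=6, seed=2)
        fit = fit_lmm(table)
        stranger = table.head(3).assign(calf_id="never_seen")
        np.testing.assert_allclose(
            fit.predict(stranger), fit.predict(stranger, use_random_effects=False)
        )
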