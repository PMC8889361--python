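"""Lower-baseline calibration and upper-limit estimation."""
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from cwsipy import (
    CalibrationError,
    ValidationError,
    calibrate,
    estimate_upper_limit,
    filter_lower_baseline_set,
    fit_lower_baseline,
    mean_canopy_temp,
)
from cwsipy.regression import fit_line
from cwsipy.synthetic import generate_baseline_points, generate_scenario

from conftest import small_scenario


def normal_equation_ols(x, y):
    """Independent closed-form OLS oracle (normal equations)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - slope * x - intercept
    r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    return slope, intercept, r2


class TestMeanCanopyTemp:
    def test_examples(self):
        assert mean_canopy_temp([30, 30, 30, 30]) == 30.0
        assert mean_canopy_temp([28, 30, 31, 29]) == 29.5

    def test_missing_direction_rejected(self):
        with pytest.raises(ValidationError):
            mean_canopy_temp([28, 30, 31, np.nan])
        with pytest.raises(ValidationError):
            mean_canopy_temp([28, 30, 31])


def _obs(regime, dsi, hour=14, plot="p1", day=1):
    return {
        "plot_id": plot,
        "regime": regime,
        "days_since_irrigation": dsi,
        "timestamp": datetime(2018, 5, day, hour, 0),
    }


class TestLowerBaselineFilter:
    def test_keeps_only_wellwatered_day3_midday(self):
        rows = (
            [_obs("well_watered", 3, day=d) for d in range(1, 5)]
            + [_obs("well_watered", 2, day=d) for d in range(5, 11)]
            + [_obs("severe", 3, day=12)]
            + [_obs("well_watered", 3, hour=10, day=13)]
        )
        out = filter_lower_baseline_set(pd.DataFrame(rows))
        assert len(out) == 4

    def test_empty_selection_is_calibration_error(self):
        all_unirrigated = pd.DataFrame([_obs("unirrigated", 3)])
        with pytest.raises(CalibrationError):
            filter_lower_baseline_set(all_unirrigated)
        none_at_day3 = pd.DataFrame(
            [_obs("well_watered", d) for d in (1, 2, 4)]
        )
        with pytest.raises(CalibrationError):
            filter_lower_baseline_set(none_at_day3)


class TestLowerBaselineFit:
    @pytest.mark.parametrize(
        "slope, intercept",
        [(-0.85, 0.75), (-0.87, 0.57)],  # published Goldasht 2017/2018 lines
    )
    def test_collinear_points_reproduce_published_coefficients(self, slope, intercept):
        vpd = np.array([1.0, 2.0, 3.5, 5.0, 6.5])
        fit = fit_lower_baseline(vpd, slope * vpd + intercept)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        for n in (5, 37, 100):
            x = rng.uniform(0.5, 7, n)
            y = -1.0 * x + 0.5 + rng.normal(0, 0.4, n)
            fit = fit_lower_baseline(x, y)
            slope, intercept, r2 = normal_equation_ols(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)
            assert fit.r2 == pytest.approx(r2, abs=1e-9)

    def test_degenerate_vpd_rejected(self):
        with pytest.raises(CalibrationError):
            fit_lower_baseline([2.0, 2.0, 2.0], [0.1, 0.2, 0.3])
        with pytest.raises(CalibrationError):
            fit_lower_baseline([1.0, 2.0], [0.1, 0.2])

    def test_positive_slope_warns_but_fits(self):
        with pytest.warns(UserWarning, match="anomalous"):
            fit = fit_lower_baseline([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert fit.slope == pytest.approx(1.0)

    def test_parameter_recovery_over_seeded_samples(self):
        slope_errs, intercept_errs = [], []
        for seed in range(50):
            pts = generate_baseline_points(-1.07, 0.6, n=200, noise_sd=0.3, seed=seed)
            fit = fit_lower_baseline(pts["vpd_kpa"], pts["tc_minus_ta"])
            slope_errs.append(abs(fit.slope - (-1.07)))
            intercept_errs.append(abs(fit.intercept - 0.6))
        assert np.mean(slope_errs) < 0.05
        assert np.mean(intercept_errs) < 0.1


def _upper_df(values, regime="unirrigated", hour=14):
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(len(values))],
            "regime": regime,
            "timestamp": [datetime(2018, 6, 1, hour, 0)] * len(values),
            "tc_mean": np.asarray(values) + 35.0,
            "air_temp_c": 35.0,
        }
    )


class TestUpperLimit:
    @pytest.mark.parametrize("plateau", [7.8, 11.5])  # published degenerate plateaus
    def test_degenerate_plateau(self, plateau):
        value, n = estimate_upper_limit(_upper_df([plateau] * 8))
        assert value == pytest.approx(plateau)
        assert n == 8

    def test_upper_decile_mean_matches_brute_force(self):
        values = [5, 6, 7, 8, 9, 10, 10, 10, 10, 10]
        value, n = estimate_upper_limit(_upper_df(values))
        # brute force: top ceil(0.1*10)=1 value
        assert value == pytest.approx(10.0)
        assert n == 10

    def test_order_invariant(self):
        values = [3.0, 9.5, 7.7, 8.8, 4.2, 9.9, 6.1]
        a, _ = estimate_upper_limit(_upper_df(values))
        b, _ = estimate_upper_limit(_upper_df(values[::-1]))
        assert a == pytest.approx(b)

    def test_duplicate_records_rejected_not_double_counted(self):
        df = _upper_df([7.0] * 6)
        df.loc[5, "plot_id"] = df.loc[0, "plot_id"]  # same plot+timestamp twice
        with pytest.raises(ValidationError):
            estimate_upper_limit(df)

    def test_too_few_observations(self):
        with pytest.raises(CalibrationError):
            estimate_upper_limit(_upper_df([7.0] * 4))

    def test_outside_window_excluded(self):
        with pytest.raises(CalibrationError):
            estimate_upper_limit(_upper_df([7.0] * 8, hour=10))


class TestCalibratePipeline:
    def test_recovers_truth_on_synthetic_experiment(self):
        cfg = small_scenario(seed=7, n_replicates=4)
        data = generate_scenario(cfg)
        models = calibrate(data.observations)
        assert len(models) == 1
        row = models.iloc[0]
        truth = cfg.cultivars[0].baselines["2017"]
        assert row["slope_a"] == pytest.approx(truth.slope_a, abs=0.15)
        assert row["intercept_b"] == pytest.approx(truth.intercept_b, abs=0.5)
        # plateau estimator carries a known positive bias ~1.75 sigma
        assert row["upper_limit"] == pytest.approx(truth.upper_limit, abs=1.0)
        assert row["fit_r2"] > 0.9
        assert row["n_lower_obs"] >= 3 and row["n_upper_obs"] >= 5

    def test_fullpipeline_slope_recovery_over_seeds(self):
        errs = []
        for seed in range(10):
            data = generate_scenario(small_scenario(seed=seed, n_replicates=4))
            models = calibrate(data.observations)
            errs.append(abs(models.iloc[0]["slope_a"] - (-0.85)))
        assert np.mean(errs) < 0.05

    def test_duplicate_observations_rejected(self):
        data = generate_scenario(small_scenario(seed=1))
        obs = pd.concat([data.observations, data.observations.iloc[[0]]])
        with pytest.raises(ValidationError):
            calibrate(obs)


def test_shared_ols_core_also_used_by_relationships():
    x = np.array([0.1, 0.3, 0.5, 0.8])
    y = 2.0 * x - 1.0
    fit = fit_line(x, y)
    assert (fit.slope, fit.intercept) == pytest.approx((2.0, -1.0), abs=1e-12)
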