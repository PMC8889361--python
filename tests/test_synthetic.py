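"""The virtual field experiment: determinism, inversion identities, closure."""
import numpy as np
import pandas as pd
import pytest

from cwsipy import PipelineConfig, ValidationError, run_pipeline
from cwsipy.psychro import add_vpd_columns
from cwsipy.synthetic import (
    ScenarioConfig,
    default_scenario,
    generate_scenario,
    generate_traits,
    generate_weather,
)

from conftest import small_scenario


def _noiseless(seed=0, **overrides):
    return small_scenario(
        seed=seed,
        noise_tc=0.0,
        directional_jitter=0.0,
        noise_ta=0.0,
        noise_rh=0.0,
        noise_yield=0.0,
        noise_rwc=0.0,
        **overrides,
    )


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tables(self):
        a = generate_scenario(small_scenario(seed=5))
        b = generate_scenario(small_scenario(seed=5))
        for name in ("weather", "observations", "events", "traits"):
            assert getattr(a, name).to_csv(index=False) == getattr(b, name).to_csv(index=False)

    def test_different_seed_differs(self):
        a = generate_scenario(small_scenario(seed=5))
        b = generate_scenario(small_scenario(seed=6))
        assert not a.observations["tc_n"].equals(b.observations["tc_n"])

    def test_yaml_roundtrip_preserves_config(self, tmp_path):
        cfg = default_scenario(seed=3)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        assert ScenarioConfig.from_yaml(path) == cfg


class TestWeather:
    def test_midday_temperature_rises_over_the_season(self):
        rng = np.random.default_rng(0)
        wx = generate_weather(default_scenario(0), "2017", rng)
        months = pd.to_datetime(wx["date"]).dt.month
        april = wx.loc[months == 4, "air_temp_c"].mean()
        july = wx.loc[months == 7, "air_temp_c"].mean()
        assert july > april

    def test_humidity_declines_over_the_season(self):
        rng = np.random.default_rng(0)
        wx = generate_weather(default_scenario(0), "2017", rng)
        months = pd.to_datetime(wx["date"]).dt.month
        assert wx.loc[months == 7, "rh_pct"].mean() < wx.loc[months == 4, "rh_pct"].mean()

    def test_zero_variance_hits_the_envelope_anchors_exactly(self):
        cfg = _noiseless()
        rng = np.random.default_rng(0)
        wx = generate_weather(cfg, "2017", rng).set_index("date")
        # mid-month anchor values from the configured envelope
        for month, expected in cfg.ta_envelope["2017"].items():
            assert wx.loc[f"2018-{month:02d}-15", "air_temp_c"] == pytest.approx(expected)


class TestInversionIdentities:
    def test_noiseless_calibration_events_lie_on_the_lower_baseline(self):
        cfg = _noiseless()
        obs = generate_scenario(cfg).observations
        truth = cfg.cultivars[0].baselines["2017"]
        sel = obs[(obs["regime"] == "well_watered") & (obs["days_since_irrigation"] == 3)]
        assert len(sel) > 0
        sel = add_vpd_columns(sel)
        dtc = sel[["tc_n", "tc_s", "tc_e", "tc_w"]].mean(axis=1) - sel["air_temp_c"]
        expected = truth.slope_a * sel["vpd_kpa"] + truth.intercept_b
        assert np.allclose(dtc, expected, atol=1e-9)

    def test_noiseless_unirrigated_events_sit_at_the_upper_limit(self):
        cfg = _noiseless()
        obs = generate_scenario(cfg).observations
        truth = cfg.cultivars[0].baselines["2017"]
        sel = obs[obs["regime"] == "unirrigated"]
        dtc = sel[["tc_n", "tc_s", "tc_e", "tc_w"]].mean(axis=1) - sel["air_temp_c"]
        assert np.allclose(dtc, truth.upper_limit, atol=1e-9)

    def test_trait_generation_at_known_stress_levels(self):
        cfg = _noiseless()
        plot_cwsi = pd.DataFrame(
            {
                "plot_id": ["a", "b"],
                "cultivar": "Goldasht",
                "regime": "well_watered",
                "year": "2017",
                "seasonal_cwsi": [0.0, 0.5],
            }
        )
        rng = np.random.default_rng(0)
        traits = generate_traits(cfg, plot_cwsi, rng).set_index("plot_id")
        assert traits.loc["a", "seed_yield_gm2"] == pytest.approx(1601.3)
        assert traits.loc["b", "rwc_pct"] == pytest.approx(-79.129 * 0.5 + 81.316)

    def test_color_score_monotone_nonincreasing_in_cwsi(self):
        cfg = _noiseless()
        grid = np.linspace(0, 1, 41)
        plot_cwsi = pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(len(grid))],
                "cultivar": "Goldasht",
                "regime": "well_watered",
                "year": "2017",
                "seasonal_cwsi": grid,
            }
        )
        traits = generate_traits(cfg, plot_cwsi, np.random.default_rng(0))
        scores = traits["color_score"].to_numpy()
        assert np.all(np.diff(scores) <= 0)
        assert scores[0] == 9 and scores[-1] == 1


class TestClosure:
    def test_noiseless_pipeline_seasonal_cwsi_decreases_with_fc_fraction(self, tmp_path):
        res = run_pipeline(PipelineConfig(outdir=tmp_path / "o", scenario=_noiseless()))
        seas = res.summary.set_index("regime")["seasonal_cwsi"]
        assert (
            seas["well_watered"] < seas["mild"] < seas["severe"] < seas["most_severe"]
        )

    def test_water_totals_proportional_to_fc_fraction(self):
        data = generate_scenario(small_scenario(seed=2))
        t = data.traits.groupby("regime")["water_total_mm"].first()
        assert t["mild"] / t["well_watered"] == pytest.approx(0.75, abs=0.01)
        assert t["most_severe"] / t["well_watered"] == pytest.approx(0.25, abs=0.01)

    def test_interval_below_calibration_day_rejected(self):
        with pytest.raises(ValidationError):
            small_scenario(measurement_interval_days=2)
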