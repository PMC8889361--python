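"""Virtual split-plot field experiment for end-to-end pipeline testing.

The generator emulates the study design — 2 cultivars x 4 deficit-irrigation
regimes (+ an unirrigated reference) x 4 replicates x 2 growing seasons,
with midday thermometry every ~3 days from April to July — by *inverting*
the CWSI definition rather than simulating canopy energy balance: a plot's
true stress trajectory c(t) is prescribed per regime, and the canopy-air
temperature difference is generated as

    Tc - Ta = c(t) * (ul - ll(VPD)) + ll(VPD) + noise

from the cultivar-year's true lower baseline ll(VPD) = a*VPD + b and upper
limit ul. Midday air temperature follows the site's monthly maximum-
temperature envelope; relative humidity declines over the season. Traits
(seed yield, RWC, color score, water total) derive from the plot's seasonal
CWSI through the configured linear relations. The point is to exercise the
pipeline's statistics, not to model crop physics.

Default scenario constants are the published study values: lower baselines
and upper limits per cultivar-year, per-regime seasonal CWSI targets (mean
of the printed cultivar-year seasonal means), the CWSI-yield and CWSI-RWC
lines, and the well-watered water totals. A fixed seed gives byte-identical
output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference as ref
from .errors import ValidationError
from .water_budget import REGIME_FRACTIONS

__all__ = [
    "BaselineTruth",
    "CultivarTruth",
    "RegimeTruth",
    "ScenarioConfig",
    "ScenarioData",
    "default_scenario",
    "generate_weather",
    "generate_observations",
    "generate_events",
    "generate_traits",
    "generate_leaf_weights",
    "generate_scenario",
    "generate_baseline_points",
    "true_cwsi",
]


@dataclass(frozen=True)
class BaselineTruth:
    """Ground-truth baseline parameters for one cultivar-year."""

    slope_a: float  # degC / kPa, < 0
    intercept_b: float  # degC
    upper_limit: float  # degC

    def __post_init__(self):
        if self.slope_a >= 0:
            raise ValidationError(f"true slope {self.slope_a} must be negative")
        if self.upper_limit <= self.intercept_b:
            raise ValidationError("upper limit must exceed the baseline intercept")

    def lower_limit_at(self, vpd):
        return self.slope_a * np.asarray(vpd, dtype=float) + self.intercept_b


@dataclass(frozen=True)
class CultivarTruth:
    label: str
    baselines: Mapping[str, BaselineTruth]  # year -> truth
    base_water_mm: Mapping[str, float]  # year -> well-watered irrigation total


@dataclass(frozen=True)
class RegimeTruth:
    label: str
    fc_fraction: float | None  # None for the unirrigated reference
    target_seasonal_cwsi: float

    def __post_init__(self):
        if self.fc_fraction is not None and not 0 < self.fc_fraction <= 1:
            raise ValidationError(f"fc_fraction {self.fc_fraction} outside (0, 1]")
        if not 0 <= self.target_seasonal_cwsi <= 1:
            raise ValidationError("target_seasonal_cwsi outside [0, 1]")


#: Days after irrigation on which the lower-baseline protocol samples the
#: well-watered plots; those events are generated non-stressed (CWSI 0).
CALIBRATION_DAY = 3

#: Color-score thresholds: score for the first upper bound the seasonal CWSI
#: falls under (monotone nonincreasing in CWSI).
DEFAULT_COLOR_THRESHOLDS = (
    (0.05, 9), (0.12, 8), (0.18, 7), (0.24, 6), (0.32, 5),
    (0.45, 4), (0.58, 3), (0.70, 2), (1.01, 1),
)

#: Seasonal mid-month RH anchors (%), April..July (semi-arid decline).
DEFAULT_RH_ENVELOPE = {4: 45.0, 5: 35.0, 6: 25.0, 7: 18.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one virtual experiment."""

    cultivars: Sequence[CultivarTruth]
    regimes: Sequence[RegimeTruth]
    years: Sequence[str]
    season_start: tuple[int, int] = (4, 1)  # (month, day), inclusive
    season_end: tuple[int, int] = (7, 31)
    measurement_interval_days: int = 3
    n_replicates: int = 4
    noise_tc: float = 0.3  # degC sd of the canopy event mean
    directional_jitter: float = 0.2  # degC sd of each N/S/E/W reading
    noise_ta: float = 1.5  # degC sd of daily midday air temperature
    noise_rh: float = 5.0  # percentage-point sd of daily midday RH
    noise_yield: float = 50.0  # g m^-2
    noise_rwc: float = 2.0  # percentage points
    yield_relation: tuple[float, float] = ref.TRAIT_RELATIONS["seed_yield_gm2"]
    rwc_relation: tuple[float, float] = ref.TRAIT_RELATIONS["rwc_pct"]
    color_thresholds: Sequence[tuple[float, int]] = DEFAULT_COLOR_THRESHOLDS
    ta_envelope: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {y: dict(v) for y, v in ref.MAX_TEMP_ENVELOPE.items()}
    )
    rh_envelope: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RH_ENVELOPE)
    )
    rainfall_mm: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {"2017": {}, "2018": {4: 4.4}}
    )  # year -> {month: in-season rainfall}
    irrigation_every_days: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.measurement_interval_days < CALIBRATION_DAY:
            raise ValidationError(
                "measurement_interval_days must be >= 3 so that day-3 "
                "well-watered calibration events occur"
            )
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cultivars": [
                {
                    "label": c.label,
                    "baselines": {
                        y: [b.slope_a, b.intercept_b, b.upper_limit]
                        for y, b in c.baselines.items()
                    },
                    "base_water_mm": dict(c.base_water_mm),
                }
                for c in self.cultivars
            ],
            "regimes": [
                {
                    "label": r.label,
                    "fc_fraction": r.fc_fraction,
                    "target_seasonal_cwsi": r.target_seasonal_cwsi,
                }
                for r in self.regimes
            ],
            "years": list(self.years),
            "season_start": list(self.season_start),
            "season_end": list(self.season_end),
            "measurement_interval_days": self.measurement_interval_days,
            "n_replicates": self.n_replicates,
            "noise_tc": self.noise_tc,
            "directional_jitter": self.directional_jitter,
            "noise_ta": self.noise_ta,
            "noise_rh": self.noise_rh,
            "noise_yield": self.noise_yield,
            "noise_rwc": self.noise_rwc,
            "yield_relation": list(self.yield_relation),
            "rwc_relation": list(self.rwc_relation),
            "color_thresholds": [list(t) for t in self.color_thresholds],
            "ta_envelope": {y: dict(v) for y, v in self.ta_envelope.items()},
            "rh_envelope": dict(self.rh_envelope),
            "rainfall_mm": {y: dict(v) for y, v in self.rainfall_mm.items()},
            "irrigation_every_days": self.irrigation_every_days,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        cultivars = [
            CultivarTruth(
                label=c["label"],
                baselines={
                    str(y): BaselineTruth(*map(float, abc))
                    for y, abc in c["baselines"].items()
                },
                base_water_mm={str(y): float(v) for y, v in c["base_water_mm"].items()},
            )
            for c in d["cultivars"]
        ]
        regimes = [
            RegimeTruth(
                label=r["label"],
                fc_fraction=None if r["fc_fraction"] is None else float(r["fc_fraction"]),
                target_seasonal_cwsi=float(r["target_seasonal_cwsi"]),
            )
            for r in d["regimes"]
        ]
        kwargs = dict(
            cultivars=cultivars,
            regimes=regimes,
            years=[str(y) for y in d["years"]],
        )
        for key in (
            "measurement_interval_days", "n_replicates", "noise_tc",
            "directional_jitter", "noise_ta", "noise_rh", "noise_yield",
            "noise_rwc", "irrigation_every_days", "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "season_start" in d:
            kwargs["season_start"] = tuple(d["season_start"])
        if "season_end" in d:
            kwargs["season_end"] = tuple(d["season_end"])
        if "yield_relation" in d:
            kwargs["yield_relation"] = tuple(d["yield_relation"])
        if "rwc_relation" in d:
            kwargs["rwc_relation"] = tuple(d["rwc_relation"])
        if "color_thresholds" in d:
            kwargs["color_thresholds"] = tuple(tuple(t) for t in d["color_thresholds"])
        if "ta_envelope" in d:
            kwargs["ta_envelope"] = {
                str(y): {int(m): float(v) for m, v in env.items()}
                for y, env in d["ta_envelope"].items()
            }
        if "rh_envelope" in d:
            kwargs["rh_envelope"] = {int(m): float(v) for m, v in d["rh_envelope"].items()}
        if "rainfall_mm" in d:
            kwargs["rainfall_mm"] = {
                str(y): {int(m): float(v) for m, v in env.items()}
                for y, env in d["rainfall_mm"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The study-shaped default: published baselines, regimes and targets.

    Per-regime seasonal-CWSI targets are the means of the four printed
    cultivar-year seasonal values for that regime.
    """

    def target(regime):
        vals = [ref.SEASONAL_CWSI[(regime, c, y)] for c in ref.CULTIVARS for y in ref.YEARS]
        return sum(vals) / len(vals)

    cultivars = [
        CultivarTruth(
            label="Goldasht",
            baselines={
                y: BaselineTruth(*ref.LOWER_BASELINES[("Goldasht", y)],
                                 ref.UPPER_LIMITS[("Goldasht", y)])
                for y in ref.YEARS
            },
            base_water_mm={"2017": 570.3, "2018": 595.0},
        ),
        CultivarTruth(
            label="Local Isfahan",
            baselines={
                y: BaselineTruth(*ref.LOWER_BASELINES[("Local Isfahan", y)],
                                 ref.UPPER_LIMITS[("Local Isfahan", y)])
                for y in ref.YEARS
            },
            base_water_mm={"2017": 610.0, "2018": 633.0},
        ),
    ]
    regimes = [
        RegimeTruth("well_watered", REGIME_FRACTIONS["well_watered"], target("well_watered")),
        RegimeTruth("mild", REGIME_FRACTIONS["mild"], target("mild")),
        RegimeTruth("severe", REGIME_FRACTIONS["severe"], target("severe")),
        RegimeTruth("most_severe", REGIME_FRACTIONS["most_severe"], target("most_severe")),
        RegimeTruth("unirrigated", None, 1.0),
    ]
    return ScenarioConfig(cultivars=cultivars, regimes=regimes, years=list(ref.YEARS), seed=seed)


# ---------------------------------------------------------------------------
# stage 1: weather

def _season_dates(config: ScenarioConfig, year: str) -> pd.DatetimeIndex:
    y = int(year) + 1  # '2017' growing season spans Dec 2017 - Jul 2018; the
    # stress season (April-July) falls in the following calendar year
    start = date(y, *config.season_start)
    end = date(y, *config.season_end)
    return pd.date_range(start, end, freq="D")


def _envelope(dates: pd.DatetimeIndex, anchors: Mapping[int, float]) -> np.ndarray:
    """Piecewise-linear interpolation through mid-month anchor values."""
    months = sorted(anchors)
    xs = [date(dates[0].year, m, 15).toordinal() for m in months]
    ys = [anchors[m] for m in months]
    t = np.array([d.toordinal() for d in dates.date])
    return np.interp(t, xs, ys)


def generate_weather(config: ScenarioConfig, year: str, rng: np.random.Generator) -> pd.DataFrame:
    """Daily midday air temperature and RH for one growing season.

    With all weather noise at zero the series is exactly the interpolated
    envelope: Ta rising and RH falling across the season.
    """
    dates = _season_dates(config, year)
    ta = _envelope(dates, config.ta_envelope[year]) + rng.normal(0, 1, len(dates)) * config.noise_ta
    rh = _envelope(dates, config.rh_envelope) + rng.normal(0, 1, len(dates)) * config.noise_rh
    rh = np.clip(rh, 2.0, 100.0)
    return pd.DataFrame(
        {"date": dates, "year": year, "air_temp_c": ta, "rh_pct": rh}
    )


# ---------------------------------------------------------------------------
# stage 2: stress trajectories and thermometry

def true_cwsi(config: ScenarioConfig, regime: RegimeTruth, when: date, year: str) -> float:
    """Prescribed stress at a date: linear from 0.6x to 1.4x the seasonal
    target across the season (mirroring the observed month-over-month rise),
    clipped to [0, 1]. The unirrigated reference is pinned at 1."""
    if regime.fc_fraction is None:
        return 1.0
    dates = _season_dates(config, year)
    t0, t1 = dates[0].date(), dates[-1].date()
    frac = (when - t0).days / (t1 - t0).days
    c = regime.target_seasonal_cwsi * (0.6 + 0.8 * frac)
    return float(np.clip(c, 0.0, 1.0))


def event_true_cwsi(
    config: ScenarioConfig, regime: RegimeTruth, when: date, year: str, event_index: int
) -> float:
    """Prescribed stress of one measurement event.

    Well-watered plots transpire at potential right after irrigation, so
    their day-3 (calibration) events sit exactly on the lower baseline
    (CWSI 0); the regime's stress is carried by the between-irrigation
    events, rescaled so the cycle mean stays on the trajectory. Other
    regimes follow the trajectory directly.
    """
    c = true_cwsi(config, regime, when, year)
    m = config.measurement_interval_days
    if regime.label != "well_watered":
        return c
    dsi = (event_index % m) + 1
    if dsi == CALIBRATION_DAY:
        return 0.0
    return float(np.clip(c * m / (m - 1), 0.0, 1.0))


def _plot_id(cultivar: str, regime: str, rep: int) -> str:
    code = "".join(w[0] for w in cultivar.split()).upper()
    return f"{code}-{regime}-r{rep}"


def generate_observations(
    config: ScenarioConfig, weather: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Thermometry log for every plot and measurement day.

    Regular plots are read once per measurement day at 13:30 with
    days_since_irrigation cycling 1..interval (so well-watered day-3 events
    recur); unirrigated plots are read half-hourly 13:00-15:00 for the
    upper-limit protocol. Four directional canopy readings share the event
    mean plus small jitter.
    """
    wx = weather.set_index(["year", weather["date"].dt.date])
    rows = []
    for year in config.years:
        dates = _season_dates(config, year)
        mdays = [d.date() for d in dates[:: config.measurement_interval_days]]
        for cult in config.cultivars:
            truth = cult.baselines[year]
            for regime in config.regimes:
                for rep in range(1, config.n_replicates + 1):
                    pid = _plot_id(cult.label, regime.label, rep)
                    for k, day in enumerate(mdays):
                        w = wx.loc[(year, day)]
                        ta, rh = float(w["air_temp_c"]), float(w["rh_pct"])
                        es = 0.6108 * np.exp(17.27 * ta / (ta + 237.3))
                        vpd = es * (1 - rh / 100.0)
                        ll = float(truth.lower_limit_at(vpd))
                        c = event_true_cwsi(config, regime, day, year, k)
                        dtc = c * (truth.upper_limit - ll) + ll
                        dsi = (k % config.measurement_interval_days) + 1
                        times = (
                            [time(13, 0), time(13, 30), time(14, 0), time(14, 30), time(15, 0)]
                            if regime.fc_fraction is None
                            else [time(13, 30)]
                        )
                        for tod in times:
                            event = ta + dtc + rng.normal(0, 1) * config.noise_tc
                            tc = event + rng.normal(0, 1, 4) * config.directional_jitter
                            rows.append(
                                (
                                    pid, cult.label, regime.label, year,
                                    datetime.combine(day, tod),
                                    tc[0], tc[1], tc[2], tc[3], ta, rh, dsi,
                                )
                            )
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id", "cultivar", "regime", "year", "timestamp",
            "tc_n", "tc_s", "tc_e", "tc_w", "air_temp_c", "rh_pct",
            "days_since_irrigation",
        ],
    )


# ---------------------------------------------------------------------------
# stage 3: water events and traits

def generate_events(config: ScenarioConfig) -> pd.DataFrame:
    """Irrigation/rainfall event table per plot (deterministic schedule).

    Irrigation events recur every ``irrigation_every_days`` across the
    season; each delivers the regime fraction of the cultivar-year's
    well-watered per-event depth. Rainfall follows the fixed monthly
    schedule and is shared by all plots.
    """
    rows = []
    for year in config.years:
        dates = _season_dates(config, year)
        irr_days = [d.date() for d in dates[:: config.irrigation_every_days]]
        rain = config.rainfall_mm.get(year, {})
        for cult in config.cultivars:
            per_event_full = cult.base_water_mm[year] / len(irr_days)
            for regime in config.regimes:
                if regime.fc_fraction is None:
                    continue
                for rep in range(1, config.n_replicates + 1):
                    pid = _plot_id(cult.label, regime.label, rep)
                    for day in irr_days:
                        rows.append(
                            (pid, cult.label, regime.label, year, day,
                             "irrigation", regime.fc_fraction * per_event_full)
                        )
                    for month, mm in rain.items():
                        rows.append(
                            (pid, cult.label, regime.label, year,
                             date(int(year) + 1, month, 15), "rainfall", mm)
                        )
    return pd.DataFrame(
        rows,
        columns=["plot_id", "cultivar", "regime", "year", "date", "kind", "mm"],
    )


def _color_from_cwsi(cwsi: float, thresholds) -> int:
    for upper, score in thresholds:
        if cwsi < upper:
            return score
    return thresholds[-1][1]


def generate_traits(
    config: ScenarioConfig, plot_cwsi: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-plot-year traits from seasonal CWSI through the linear relations.

    ``plot_cwsi`` needs columns plot_id, cultivar, regime, year,
    seasonal_cwsi. Yields and RWC get Gaussian noise; the color score is a
    deterministic monotone step function of CWSI; water totals are the
    regime fraction of the cultivar-year irrigation base plus rainfall.
    """
    ys, yi = config.yield_relation
    rs, ri = config.rwc_relation
    frac = {r.label: r.fc_fraction for r in config.regimes}
    base = {
        (c.label, y): c.base_water_mm[y] for c in config.cultivars for y in config.years
    }
    rain = {y: sum(config.rainfall_mm.get(y, {}).values()) for y in config.years}
    rows = []
    for rec in plot_cwsi.itertuples(index=False):
        if frac.get(rec.regime) is None:
            continue
        c = float(rec.seasonal_cwsi)
        seed_yield = max(0.0, ys * c + yi + rng.normal(0, 1) * config.noise_yield)
        rwc = float(np.clip(rs * c + ri + rng.normal(0, 1) * config.noise_rwc, 0.0, 100.0))
        water = frac[rec.regime] * base[(rec.cultivar, rec.year)] + rain[rec.year]
        rows.append(
            (
                rec.plot_id, rec.cultivar, rec.regime, rec.year, c,
                rwc, _color_from_cwsi(c, config.color_thresholds),
                seed_yield, water, seed_yield / water,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id", "cultivar", "regime", "year", "seasonal_cwsi",
            "rwc_pct", "color_score", "seed_yield_gm2", "water_total_mm", "wue",
        ],
    )


def generate_leaf_weights(traits: pd.DataFrame, dry_g: float = 0.10, turgid_g: float = 0.60) -> pd.DataFrame:
    """Leaf-disc weight table whose RWC reproduces the trait RWC exactly.

    FW = DW + (RWC/100)*(TW - DW) for fixed disc dry/turgid weights (g).
    """
    out = traits[["plot_id", "cultivar", "regime", "year", "rwc_pct"]].copy()
    out["dw_g"] = dry_g
    out["tw_g"] = turgid_g
    out["fw_g"] = dry_g + out["rwc_pct"] / 100.0 * (turgid_g - dry_g)
    return out.drop(columns="rwc_pct")


# ---------------------------------------------------------------------------
# whole scenario

@dataclass(frozen=True)
class ScenarioData:
    """All tables of one generated experiment plus the generating truth."""

    config: ScenarioConfig
    weather: pd.DataFrame
    observations: pd.DataFrame
    events: pd.DataFrame
    plot_seasonal_cwsi: pd.DataFrame  # true (prescribed) per plot-year
    traits: pd.DataFrame
    leaf_weights: pd.DataFrame


def _true_plot_seasonal(config: ScenarioConfig) -> pd.DataFrame:
    """Prescribed seasonal CWSI per plot-year: mean of the four monthly
    means of the trajectory sampled on measurement days (the same statistic
    the pipeline computes)."""
    rows = []
    for year in config.years:
        dates = _season_dates(config, year)
        mdays = [d.date() for d in dates[:: config.measurement_interval_days]]
        for cult in config.cultivars:
            for regime in config.regimes:
                by_month: dict[int, list[float]] = {}
                for k, day in enumerate(mdays):
                    by_month.setdefault(day.month, []).append(
                        event_true_cwsi(config, regime, day, year, k)
                    )
                monthly = [np.mean(v) for v in by_month.values()]
                seasonal = float(np.mean(monthly))
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        (_plot_id(cult.label, regime.label, rep),
                         cult.label, regime.label, year, seasonal)
                    )
    return pd.DataFrame(
        rows, columns=["plot_id", "cultivar", "regime", "year", "seasonal_cwsi"]
    )


def generate_scenario(config: ScenarioConfig) -> ScenarioData:
    """Generate the full virtual experiment (deterministic under the seed)."""
    rng = np.random.default_rng(config.seed)
    weather = pd.concat(
        [generate_weather(config, y, rng) for y in config.years], ignore_index=True
    )
    observations = generate_observations(config, weather, rng)
    events = generate_events(config)
    plot_cwsi = _true_plot_seasonal(config)
    traits = generate_traits(config, plot_cwsi, rng)
    leaf_weights = generate_leaf_weights(traits)
    return ScenarioData(
        config=config,
        weather=weather,
        observations=observations,
        events=events,
        plot_seasonal_cwsi=plot_cwsi,
        traits=traits,
        leaf_weights=leaf_weights,
    )


# ---------------------------------------------------------------------------
# small helper for calibration experiments

def generate_baseline_points(
    slope: float,
    intercept: float,
    n: int = 200,
    noise_sd: float = 0.3,
    seed: int = 0,
    vpd_range: tuple[float, float] = (1.0, 6.0),
) -> pd.DataFrame:
    """(VPD, Tc-Ta) samples on a known lower baseline with Gaussian noise."""
    rng = np.random.default_rng(seed)
    vpd = rng.uniform(*vpd_range, n)
    dtc = slope * vpd + intercept + rng.normal(0, 1, n) * noise_sd
    return pd.DataFrame({"vpd_kpa": vpd, "tc_minus_ta": dtc})
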