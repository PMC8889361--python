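"""Per-observation CWSI and monthly/seasonal aggregation.

The empirical crop water stress index locates the measured canopy-air
temperature difference between the calibrated references:

    CWSI = [(Tc-Ta)m - (Tc-Ta)ll] / [(Tc-Ta)ul - (Tc-Ta)ll]

with (Tc-Ta)ll = a*VPD + b from the lower baseline and (Tc-Ta)ul the
fully-stressed constant. 0 means unstressed, 1 maximally stressed. Noisy
field data can fall outside [0, 1]; values are clamped with an audit flag
and the raw value retained.

Seasonal summaries follow the report convention: an unweighted mean of the
calendar-month means over the stress season (April-July), rounded half-up to
two decimals alongside full precision.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Mapping, NamedTuple

import pandas as pd

from .baselines import BaselineModel, add_canopy_mean
from .errors import ValidationError
from .psychro import add_vpd_columns
from .regression import round_half_up

__all__ = [
    "CwsiRecord",
    "SeasonalMean",
    "DEFAULT_SEASON_MONTHS",
    "compute_cwsi",
    "compute_cwsi_table",
    "monthly_means",
    "seasonal_mean",
    "summarize",
]

#: Stress-season months included in seasonal summaries (April-July).
DEFAULT_SEASON_MONTHS = (4, 5, 6, 7)


@dataclass(frozen=True)
class CwsiRecord:
    """One observation's CWSI with its ingredients (degC, kPa, unitless)."""

    vpd: float
    tc_minus_ta_measured: float
    lower_limit_at_vpd: float
    upper_limit: float
    cwsi_raw: float
    cwsi: float
    clamped: bool
    plot_id: str = ""
    cultivar: str = ""
    regime: str = ""
    timestamp: datetime | None = None


def compute_cwsi(measured: float, vpd: float, baseline: BaselineModel) -> CwsiRecord:
    """Empirical CWSI for one measured Tc - Ta (degC) at the given VPD (kPa)."""
    ll = float(baseline.lower_limit_at(vpd))
    ul = baseline.upper_limit
    if ul <= ll:
        raise ValidationError(
            f"degenerate denominator: upper limit {ul} <= lower limit {ll:.3f} "
            f"at VPD {vpd} kPa"
        )
    raw = (measured - ll) / (ul - ll)
    cwsi = min(1.0, max(0.0, raw))
    return CwsiRecord(
        vpd=vpd,
        tc_minus_ta_measured=measured,
        lower_limit_at_vpd=ll,
        upper_limit=ul,
        cwsi_raw=raw,
        cwsi=cwsi,
        clamped=not (0.0 <= raw <= 1.0),
    )


def compute_cwsi_table(obs: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Vectorized CWSI over an observation table.

    ``baselines`` is the calibration output (one row per cultivar-year with
    slope_a, intercept_b, upper_limit). Unirrigated plots are excluded: they
    exist to calibrate the upper limit, not to be scored.
    """
    df = obs[obs["regime"] != "unirrigated"].copy()
    if "year" not in df.columns:
        df["year"] = pd.to_datetime(df["timestamp"]).dt.year.astype(str)
    if "tc_mean" not in df.columns:
        df = add_canopy_mean(df)
    if "vpd_kpa" not in df.columns:
        df = add_vpd_columns(df)
    base = baselines.copy()
    base["year"] = base["year"].astype(str)
    merged = df.merge(
        base[["cultivar", "year", "slope_a", "intercept_b", "upper_limit"]],
        on=["cultivar", "year"],
        how="left",
        validate="many_to_one",
    )
    if merged["slope_a"].isna().any():
        missing = merged.loc[merged["slope_a"].isna(), ["cultivar", "year"]]
        pairs = sorted(set(map(tuple, missing.to_numpy())))
        raise ValidationError(f"no calibrated baseline for cultivar-years: {pairs}")
    merged["tc_minus_ta"] = merged["tc_mean"] - merged["air_temp_c"]
    merged["lower_limit_at_vpd"] = (
        merged["slope_a"] * merged["vpd_kpa"] + merged["intercept_b"]
    )
    denom = merged["upper_limit"] - merged["lower_limit_at_vpd"]
    if (denom <= 0).any():
        raise ValidationError("degenerate denominator (upper <= lower) in CWSI table")
    merged["cwsi_raw"] = (merged["tc_minus_ta"] - merged["lower_limit_at_vpd"]) / denom
    merged["cwsi"] = merged["cwsi_raw"].clip(0.0, 1.0)
    merged["clamped"] = (merged["cwsi_raw"] < 0.0) | (merged["cwsi_raw"] > 1.0)
    keep = [
        "plot_id", "cultivar", "regime", "year", "timestamp", "vpd_kpa",
        "tc_minus_ta", "lower_limit_at_vpd", "upper_limit",
        "cwsi_raw", "cwsi", "clamped",
    ]
    return merged[keep]


def monthly_means(
    records: pd.DataFrame,
    by=("cultivar", "regime", "year"),
    months=DEFAULT_SEASON_MONTHS,
) -> pd.DataFrame:
    """Arithmetic mean CWSI per calendar month per group.

    Every record in a group-month weighs equally; empty months are simply
    absent. Returns columns: *by, month, cwsi_mean, n_obs.
    """
    df = records.copy()
    df["month"] = pd.to_datetime(df["timestamp"]).dt.month
    if months is not None:
        df = df[df["month"].isin(months)]
    out = (
        df.groupby([*by, "month"], sort=True)["cwsi"]
        .agg(cwsi_mean="mean", n_obs="size")
        .reset_index()
    )
    return out


class SeasonalMean(NamedTuple):
    value: float  # full precision
    rounded: float  # half-up at report precision


def seasonal_mean(monthly: Mapping[int, float] | pd.Series, decimals: int = 2) -> SeasonalMean:
    """Unweighted mean of the monthly means present (not observation-weighted)."""
    values = list(monthly.values()) if isinstance(monthly, Mapping) else list(monthly)
    if not values:
        raise ValidationError("seasonal mean of an empty monthly mapping")
    mean = sum(float(v) for v in values) / len(values)
    return SeasonalMean(mean, round_half_up(mean, decimals))


def summarize(
    records: pd.DataFrame,
    by=("cultivar", "regime", "year"),
    months=DEFAULT_SEASON_MONTHS,
    decimals: int = 2,
) -> pd.DataFrame:
    """Report-style summary: monthly-mean columns plus the seasonal mean.

    One row per group with month_<m> columns, seasonal_cwsi (full precision)
    and seasonal_cwsi_rounded.
    """
    mm = monthly_means(records, by=by, months=months)
    wide = mm.pivot_table(index=list(by), columns="month", values="cwsi_mean")
    wide.columns = [f"month_{int(m)}" for m in wide.columns]
    month_cols = list(wide.columns)
    seas = wide[month_cols].apply(
        lambda row: seasonal_mean(row.dropna(), decimals=decimals), axis=1
    )
    wide["seasonal_cwsi"] = [s.value for s in seas]
    wide["seasonal_cwsi_rounded"] = [s.rounded for s in seas]
    return wide.reset_index()
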