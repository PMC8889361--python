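"""Calibration of the non-stressed and fully-stressed canopy baselines.

The empirical CWSI needs two references per cultivar-year:

* the lower (non-stressed) baseline, a linear relation
  Tc - Ta = a*VPD + b fitted by OLS on well-watered plots measured three
  days after irrigation, and
* the upper (fully stressed) limit, a VPD-independent Tc - Ta plateau
  estimated from unirrigated plots observed between 13:00 and 15:00.

Canopy temperature is recorded in four directions (N, S, E, W) per event and
averaged into one Tc. The 13:00-15:00 midday window is applied to all
calibration observations. The upper limit is estimated as the mean of the
top decile of qualifying Tc - Ta values: a plateau estimator that is robust
to single outliers, unlike the raw maximum (the quantile is configurable).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError
from .psychro import add_vpd_columns
from .regression import LinearFit, fit_line

__all__ = [
    "BaselineModel",
    "MIDDAY_WINDOW",
    "CANOPY_COLUMNS",
    "mean_canopy_temp",
    "add_canopy_mean",
    "check_duplicates",
    "filter_lower_baseline_set",
    "fit_lower_baseline",
    "estimate_upper_limit",
    "calibrate",
]

log = logging.getLogger("cwsipy.baselines")

#: Local clock window (inclusive) for calibration-grade midday observations.
MIDDAY_WINDOW = (time(13, 0), time(15, 0))

#: Directional canopy-temperature columns (North, South, East, West).
CANOPY_COLUMNS = ("tc_n", "tc_s", "tc_e", "tc_w")

_CANOPY_RANGE = (-10.0, 70.0)


@dataclass(frozen=True)
class BaselineModel:
    """Calibrated references for one cultivar-year.

    slope_a is degC per kPa (negative for a transpiring canopy), intercept_b
    and upper_limit are degC.
    """

    cultivar: str
    year: str
    slope_a: float
    intercept_b: float
    upper_limit: float
    n_lower_obs: int
    n_upper_obs: int
    fit_r2: float

    def __post_init__(self):
        if self.upper_limit <= self.intercept_b:
            raise ValidationError(
                f"upper_limit {self.upper_limit} must exceed intercept "
                f"{self.intercept_b} ({self.cultivar} {self.year})"
            )
        if self.n_lower_obs < 3:
            raise ValidationError("a valid fit needs at least 3 lower-baseline points")

    def lower_limit_at(self, vpd):
        """Non-stressed Tc - Ta (degC) at the given VPD (kPa)."""
        return self.slope_a * np.asarray(vpd, dtype=float) + self.intercept_b


def mean_canopy_temp(readings) -> float:
    """Arithmetic mean of the four directional canopy readings (degC).

    Exactly four finite readings are required; a missing direction is an
    error rather than silently imputed.
    """
    arr = np.asarray(readings, dtype=float)
    if arr.shape != (4,):
        raise ValidationError(f"expected 4 directional readings, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("missing/non-finite canopy reading in observation")
    lo, hi = _CANOPY_RANGE
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValidationError(f"canopy temperature outside [{lo}, {hi}] degC: {arr}")
    return float(arr.mean())


def add_canopy_mean(df: pd.DataFrame) -> pd.DataFrame:
    """Append tc_mean = mean of the four directional columns (strict)."""
    missing = [c for c in CANOPY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing canopy columns: {missing}")
    block = df[list(CANOPY_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(block)):
        bad = df.index[~np.isfinite(block).all(axis=1)].tolist()[:5]
        raise ValidationError(f"missing canopy readings at rows {bad}")
    lo, hi = _CANOPY_RANGE
    if np.any(block < lo) or np.any(block > hi):
        raise ValidationError(f"canopy temperature outside [{lo}, {hi}] degC")
    out = df.copy()
    out["tc_mean"] = block.mean(axis=1)
    return out


def check_duplicates(df: pd.DataFrame, keys=("plot_id", "timestamp")) -> None:
    """Reject duplicated (plot, timestamp) records — an input error."""
    dup = df.duplicated(subset=list(keys))
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise ValidationError(f"duplicate {keys} records at rows {rows}")


def _in_window(ts: pd.Series, window) -> pd.Series:
    t0, t1 = window
    tod = pd.to_datetime(ts).dt.time
    return tod.map(lambda t: t0 <= t <= t1)


def filter_lower_baseline_set(
    df: pd.DataFrame,
    days_after: int = 3,
    window=MIDDAY_WINDOW,
) -> pd.DataFrame:
    """Select the calibration set for the non-stressed baseline.

    Well-watered observations taken exactly ``days_after`` days after an
    irrigation, within the midday window. Empty selection is a calibration
    error carrying the filter counts.
    """
    required = {"regime", "days_since_irrigation", "timestamp"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    n_in = len(df)
    ww = df[df["regime"] == "well_watered"]
    day3 = ww[ww["days_since_irrigation"].astype(int) == int(days_after)]
    out = day3[_in_window(day3["timestamp"], window)]
    log.info(
        "lower-baseline filter: %d in -> %d well-watered -> %d at day %d -> %d in window",
        n_in, len(ww), len(day3), days_after, len(out),
    )
    if out.empty:
        raise CalibrationError(
            f"no lower-baseline observations: {n_in} input, {len(ww)} well-watered, "
            f"{len(day3)} at day {days_after}, 0 inside {window[0]}-{window[1]}"
        )
    return out


def fit_lower_baseline(vpd, tc_minus_ta) -> LinearFit:
    """OLS of Tc - Ta on VPD; returns slope a, intercept b and R^2.

    A non-negative slope is physically anomalous (a transpiring canopy should
    cool as VPD rises) and produces a warning, not an error, so that
    partial-season calibrations still run.
    """
    fit = fit_line(vpd, tc_minus_ta)
    if fit.slope >= 0:
        warnings.warn(
            f"lower-baseline slope {fit.slope:.3f} >= 0 is physically anomalous",
            stacklevel=2,
        )
    return fit


def estimate_upper_limit(
    df: pd.DataFrame,
    window=MIDDAY_WINDOW,
    quantile: float = 0.10,
    min_obs: int = 5,
) -> tuple[float, int]:
    """Fully-stressed (Tc - Ta)ul plateau from unirrigated observations.

    Restricts to regime == 'unirrigated' within the midday window and
    returns (mean of the top ``quantile`` fraction of Tc - Ta, number of
    qualifying observations). Order-invariant; duplicated records are
    rejected rather than double-counted.
    """
    if not 0 < quantile <= 1:
        raise ValidationError("quantile must be in (0, 1]")
    check_duplicates(df)
    sub = df[df["regime"] == "unirrigated"]
    sub = sub[_in_window(sub["timestamp"], window)]
    if "tc_mean" not in sub.columns:
        sub = add_canopy_mean(sub)
    n = len(sub)
    if n < min_obs:
        raise CalibrationError(
            f"only {n} qualifying unirrigated observations (need >= {min_obs})"
        )
    dtc = np.sort(sub["tc_mean"].to_numpy(dtype=float) - sub["air_temp_c"].to_numpy(dtype=float))
    k = max(1, math.ceil(quantile * n))
    return float(dtc[-k:].mean()), n


def calibrate(
    df: pd.DataFrame,
    group=("cultivar", "year"),
    days_after: int = 3,
    window=MIDDAY_WINDOW,
    upper_quantile: float = 0.10,
) -> pd.DataFrame:
    """Full baseline calibration per cultivar-year.

    Input is the observation table (see tables.OBSERVATION_SCHEMA); a 'year'
    column is derived from the timestamp when absent. Returns one row per
    group with slope_a, intercept_b, upper_limit, fit_r2, n_lower_obs,
    n_upper_obs.
    """
    if df.empty:
        raise CalibrationError("no observations to calibrate")
    df = df.copy()
    check_duplicates(df)
    if "year" not in df.columns:
        df["year"] = pd.to_datetime(df["timestamp"]).dt.year.astype(str)
    df = add_canopy_mean(df)
    df = add_vpd_columns(df)
    rows = []
    for key, g in df.groupby(list(group), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        lower = filter_lower_baseline_set(g, days_after=days_after, window=window)
        fit = fit_lower_baseline(
            lower["vpd_kpa"].to_numpy(),
            lower["tc_mean"].to_numpy() - lower["air_temp_c"].to_numpy(),
        )
        upper, n_upper = estimate_upper_limit(g, window=window, quantile=upper_quantile)
        model = BaselineModel(
            cultivar=str(key[0]),
            year=str(key[1]) if len(key) > 1 else "",
            slope_a=fit.slope,
            intercept_b=fit.intercept,
            upper_limit=upper,
            n_lower_obs=fit.n,
            n_upper_obs=n_upper,
            fit_r2=fit.r2,
        )
        rows.append(model.__dict__)
        log.info(
            "calibrated %s %s: a=%.3f b=%.3f ul=%.2f (n=%d/%d, R2=%.3f)",
            model.cultivar, model.year, model.slope_a, model.intercept_b,
            model.upper_limit, model.n_lower_obs, model.n_upper_obs, model.fit_r2,
        )
    return pd.DataFrame(rows)
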