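"""Psychrometrics: vapor pressure deficit from air temperature and humidity.

VPD is the x-axis of the non-stressed canopy baseline, so everything
downstream depends on this conversion. Saturation vapor pressure follows the
FAO-56 Tetens form

    es(T) = 0.6108 * exp(17.27*T / (T + 237.3))   [kPa, T in deg C]

and VPD = es(Ta) * (1 - RH/100) from the simultaneously recorded air
temperature / relative-humidity pair. Units are kPa throughout; baseline
slopes downstream are degC per kPa.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "AirState",
    "VpdValue",
    "saturation_vapor_pressure",
    "vpd_from_temp_rh",
    "add_vpd_columns",
    "FORMULA",
    "AIR_TEMP_RANGE",
]

#: Metadata tag recorded in outputs so the formula can be swapped/audited.
FORMULA = "tetens-fao56"

#: Plausible field range for air temperature (deg C); outside is rejected.
AIR_TEMP_RANGE = (-10.0, 55.0)

_TETENS_A = 0.6108  # kPa, es at 0 degC
_TETENS_B = 17.27
_TETENS_C = 237.3  # degC


@dataclass(frozen=True)
class AirState:
    """One simultaneous air temperature / relative humidity reading."""

    air_temp: float  # deg C
    relative_humidity: float  # percent, [0, 100] inclusive
    timestamp: datetime | None = None

    def __post_init__(self):
        lo, hi = AIR_TEMP_RANGE
        if not lo <= self.air_temp <= hi:
            raise ValidationError(
                f"air_temp {self.air_temp} degC outside plausible range [{lo}, {hi}]"
            )
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise ValidationError(
                f"relative_humidity {self.relative_humidity}% outside [0, 100]"
            )


@dataclass(frozen=True)
class VpdValue:
    """Vapor pressure deficit with its saturation/actual components (kPa)."""

    vpd: float
    saturation_vp: float
    actual_vp: float
    formula: str = FORMULA


def saturation_vapor_pressure(air_temp):
    """Saturation vapor pressure es(T) in kPa (Tetens / FAO-56).

    Accepts scalars or arrays; strictly increasing in T and positive over the
    accepted range.
    """
    t = np.asarray(air_temp, dtype=float)
    lo, hi = AIR_TEMP_RANGE
    if np.any(t < lo) or np.any(t > hi):
        bad = t[(t < lo) | (t > hi)]
        raise ValidationError(
            f"air temperature outside [{lo}, {hi}] degC: {np.atleast_1d(bad)[:5]}"
        )
    es = _TETENS_A * np.exp(_TETENS_B * t / (t + _TETENS_C))
    return float(es) if np.isscalar(air_temp) else es


def vpd_from_temp_rh(state: AirState) -> VpdValue:
    """VPD (kPa) from an AirState: es(Ta) * (1 - RH/100)."""
    es = saturation_vapor_pressure(state.air_temp)
    ea = es * state.relative_humidity / 100.0
    return VpdValue(vpd=es - ea, saturation_vp=es, actual_vp=ea)


def add_vpd_columns(
    df: pd.DataFrame,
    temp_col: str = "air_temp_c",
    rh_col: str = "rh_pct",
) -> pd.DataFrame:
    """Append vpd_kpa, es_kpa, ea_kpa to a table of Ta/RH readings.

    Returns a copy; input rows with RH outside [0, 100] or temperature
    outside the field range are rejected as a whole.
    """
    for col in (temp_col, rh_col):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r}")
    rh = df[rh_col].to_numpy(dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        bad_rows = df.index[(rh < 0) | (rh > 100)].tolist()[:5]
        raise ValidationError(f"relative humidity outside [0, 100] at rows {bad_rows}")
    es = saturation_vapor_pressure(df[temp_col].to_numpy(dtype=float))
    out = df.copy()
    out["es_kpa"] = es
    out["ea_kpa"] = es * rh / 100.0
    out["vpd_kpa"] = out["es_kpa"] - out["ea_kpa"]
    return out
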