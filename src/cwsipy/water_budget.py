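"""Soil-profile irrigation depth and per-plot water bookkeeping.

The refill-to-field-capacity depth over a layered profile is

    D = sum_i (theta_fc_i - theta_i) * dZ_i

with volumetric water contents theta (cm^3 cm^-3, dimensionless) and layer
thickness dZ in mm, so D is in mm directly. Deficit regimes deliver a fixed
fraction of D per irrigation event (1.00 / 0.75 / 0.50 / 0.25 of field
capacity). The water ledger accumulates irrigation and rainfall per plot;
total water consumed = irrigation + rainfall.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "REGIME_FRACTIONS",
    "irrigation_depth",
    "regime_depth",
    "accumulate_ledger",
]

#: Delivered fraction of the refill-to-FC depth per irrigation regime.
REGIME_FRACTIONS = {
    "well_watered": 1.00,
    "mild": 0.75,
    "severe": 0.50,
    "most_severe": 0.25,
}


@dataclass(frozen=True)
class SoilLayer:
    """One soil layer: field capacity, current water content, thickness (mm)."""

    theta_fc: float  # cm^3 cm^-3
    theta: float  # cm^3 cm^-3
    thickness_mm: float

    def __post_init__(self):
        if not 0 < self.theta_fc <= 0.6:
            raise ValidationError(f"theta_fc {self.theta_fc} outside (0, 0.6]")
        if self.theta <= 0:
            raise ValidationError(f"theta {self.theta} must be positive")
        if self.theta > self.theta_fc:
            raise ValidationError(
                f"supersaturated layer: theta {self.theta} > theta_fc {self.theta_fc}"
            )
        if self.thickness_mm <= 0:
            raise ValidationError(f"thickness {self.thickness_mm} mm must be positive")


@dataclass(frozen=True)
class SoilProfile:
    """Ordered soil layers, top down (typically 3 x 300 mm for 0-90 cm)."""

    layers: Sequence[SoilLayer]

    def __post_init__(self):
        if not self.layers:
            raise ValidationError("profile needs at least one layer")


def irrigation_depth(profile: SoilProfile) -> float:
    """Refill-to-field-capacity depth D (mm) summed over the profile layers."""
    return sum((l.theta_fc - l.theta) * l.thickness_mm for l in profile.layers)


def regime_depth(full_depth: float, regime_fraction: float) -> float:
    """Depth delivered by a deficit regime: fraction x refill depth (mm)."""
    if full_depth < 0:
        raise ValidationError(f"full_depth {full_depth} mm must be >= 0")
    if not 0 < regime_fraction <= 1:
        raise ValidationError(f"regime fraction {regime_fraction} outside (0, 1]")
    return regime_fraction * full_depth


def accumulate_ledger(events: pd.DataFrame) -> pd.DataFrame:
    """Per-plot water ledger from an event table (plot_id, kind, mm).

    kind is 'irrigation' or 'rainfall'; amounts are nonnegative mm. Returns
    one row per plot with irrigation_mm, rainfall_mm, total_mm. Totals are
    permutation-invariant sums.
    """
    required = {"plot_id", "kind", "mm"}
    missing = required - set(events.columns)
    if missing:
        raise ValidationError(f"missing event columns: {sorted(missing)}")
    if events.empty:
        return pd.DataFrame(columns=["plot_id", "irrigation_mm", "rainfall_mm", "total_mm"])
    bad_kind = set(events["kind"]) - {"irrigation", "rainfall"}
    if bad_kind:
        raise ValidationError(f"unknown event kinds: {sorted(bad_kind)}")
    if (events["mm"].astype(float) < 0).any():
        rows = events.index[events["mm"].astype(float) < 0].tolist()[:5]
        raise ValidationError(f"negative water amounts at rows {rows}")
    pivot = (
        events.pivot_table(
            index="plot_id", columns="kind", values="mm", aggfunc="sum", fill_value=0.0
        )
        .reindex(columns=["irrigation", "rainfall"], fill_value=0.0)
        .rename(columns={"irrigation": "irrigation_mm", "rainfall": "rainfall_mm"})
    )
    pivot["total_mm"] = pivot["irrigation_mm"] + pivot["rainfall_mm"]
    return pivot.reset_index().rename_axis(None, axis=1)
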