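"""Linear CWSI-trait relationships and irrigation-regime classification.

Seasonal CWSI relates linearly (and negatively) to water consumed, leaf RWC,
color quality, seed yield and WUE; the fitted lines double as trait
predictors (e.g. seed yield from a season's CWSI). A regime's seasonal CWSI
is classified against the recommended deficit-irrigation band (default
0.28-0.33, boundary inclusive): below it the crop was wetter than necessary
(over-irrigated), inside it the deficit is acceptable, above it the crop was
under-irrigated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .regression import fit_line

__all__ = [
    "LinearRelation",
    "RegimeVerdict",
    "DEFAULT_BAND",
    "fit_relation",
    "fit_relation_table",
    "predict_trait",
    "classify_regime",
]

#: Recommended seasonal-CWSI band for an acceptable deficit regime.
DEFAULT_BAND = (0.28, 0.33)

#: Trait columns a per-plot-year summary table may relate to seasonal CWSI.
TRAIT_RESPONSES = ("water_total_mm", "rwc_pct", "color_score", "seed_yield_gm2", "wue")


@dataclass(frozen=True)
class LinearRelation:
    """OLS relation trait = slope*CWSI + intercept.

    The p-value of the correlation t-statistic is presentation metadata
    (significance stars), not used for decisions.
    """

    predictor: str
    response: str
    slope: float
    intercept: float
    r2: float
    n: int
    p_value: float

    def __post_init__(self):
        if self.n < 3:
            raise ValidationError("a relation needs at least 3 pairs")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValidationError(f"R^2 {self.r2} outside [0, 1]")


@dataclass(frozen=True)
class RegimeVerdict:
    """Classification of a seasonal CWSI against the recommendation band."""

    seasonal_cwsi: float
    band_low: float
    band_high: float
    verdict: str  # under_irrigated | acceptable_deficit | over_irrigated


def fit_relation(
    cwsi: Sequence[float], trait_values: Sequence[float], response: str
) -> LinearRelation:
    """OLS of a trait on seasonal CWSI (same estimator as the baseline fit)."""
    fit = fit_line(cwsi, trait_values)
    return LinearRelation(
        predictor="seasonal_cwsi",
        response=response,
        slope=fit.slope,
        intercept=fit.intercept,
        r2=fit.r2,
        n=fit.n,
        p_value=fit.p_value,
    )


def fit_relation_table(
    summary: pd.DataFrame,
    predictor: str = "seasonal_cwsi",
    responses: Sequence[str] = TRAIT_RESPONSES,
) -> pd.DataFrame:
    """Fit every available trait column against seasonal CWSI.

    ``summary`` holds per-plot-year aggregates (the granularity of the
    trait measurements). Returns one row per fitted response.
    """
    rows = []
    for resp in responses:
        if resp not in summary.columns:
            continue
        sub = summary[[predictor, resp]].dropna()
        rel = fit_relation(sub[predictor], sub[resp], resp)
        rows.append(rel.__dict__)
    if not rows:
        raise ValidationError(f"no trait columns found among {list(responses)}")
    return pd.DataFrame(rows)


def predict_trait(relation: LinearRelation, cwsi: float) -> float:
    """Predicted trait value slope*cwsi + intercept for cwsi in [0, 1].

    A physically impossible negative prediction (e.g. yield extrapolated at
    extreme stress) is returned with a warning.
    """
    if not 0.0 <= cwsi <= 1.0:
        raise ValidationError(f"cwsi {cwsi} outside [0, 1]")
    value = relation.slope * cwsi + relation.intercept
    if value < 0:
        warnings.warn(
            f"predicted {relation.response} = {value:.1f} below zero at CWSI {cwsi}",
            stacklevel=2,
        )
    return value


def classify_regime(seasonal_cwsi: float, band=DEFAULT_BAND) -> RegimeVerdict:
    """Three-way, boundary-inclusive classification against the band.

    Monotone in seasonal_cwsi: raising it never moves the verdict from
    under_irrigated toward over_irrigated.
    """
    low, high = float(band[0]), float(band[1])
    if low >= high:
        raise ValidationError(f"invalid band: low {low} >= high {high}")
    if not np.isfinite(seasonal_cwsi):
        raise ValidationError("seasonal_cwsi must be finite")
    if seasonal_cwsi < low:
        verdict = "over_irrigated"
    elif seasonal_cwsi <= high:
        verdict = "acceptable_deficit"
    else:
        verdict = "under_irrigated"
    return RegimeVerdict(
        seasonal_cwsi=float(seasonal_cwsi), band_low=low, band_high=high, verdict=verdict
    )
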