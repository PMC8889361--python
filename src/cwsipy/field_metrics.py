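"""Agronomic companion metrics: RWC, Munsell color quality, WUE, reductions.

* Leaf relative water content, RWC = 100*(FW-DW)/(TW-DW), from fresh/turgid/
  dry leaf-disc weights. Protocol metadata (8 discs of 8 mm, 6 h soak,
  70 degC / 24 h drying) travels with the result but is not computation.
* Visual plant color quality: Munsell chart page + value/chroma mapped to a
  1 (yellow, dead) .. 9 (dark green) score; seasonal quality is the
  unweighted mean of the pre-stress initial score and the four monthly
  scores (April-July), reported at 1 decimal.
* Water use efficiency: seed yield (g m^-2) per total water consumed (mm).
* Percent reduction of a stressed value relative to a reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError
from .regression import round_half_up

__all__ = [
    "LeafDiscWeights",
    "RWC_PROTOCOL",
    "MUNSELL_SCORES",
    "relative_water_content",
    "munsell_score",
    "seasonal_color_mean",
    "water_use_efficiency",
    "percent_reduction",
]

#: Sampling protocol metadata for leaf-disc RWC (not used in computation).
RWC_PROTOCOL = {
    "n_discs": 8,
    "disc_diameter_mm": 8,
    "soak_hours": 6,
    "drying_temp_c": 70,
    "drying_hours": 24,
}


@dataclass(frozen=True)
class LeafDiscWeights:
    """Fresh, turgid and dry weights (g) of one leaf-disc sample."""

    fresh_weight: float
    turgid_weight: float
    dry_weight: float
    protocol: Mapping = field(default_factory=lambda: RWC_PROTOCOL)

    def __post_init__(self):
        fw, tw, dw = self.fresh_weight, self.turgid_weight, self.dry_weight
        if min(fw, tw, dw) <= 0:
            raise ValidationError("leaf-disc weights must be positive")
        if not dw <= fw <= tw:
            raise ValidationError(
                f"weights must satisfy dry <= fresh <= turgid, got "
                f"DW={dw}, FW={fw}, TW={tw}"
            )


def relative_water_content(weights: LeafDiscWeights) -> float:
    """RWC (%) = 100*(FW-DW)/(TW-DW); scale-invariant in the weights."""
    fw, tw, dw = weights.fresh_weight, weights.turgid_weight, weights.dry_weight
    if tw == dw:
        raise ValidationError("turgid weight equals dry weight: RWC undefined")
    return 100.0 * (fw - dw) / (tw - dw)


def _munsell_table() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {("5GY", "3/4"): 9, ("5GY", "4/4"): 8}
    for chroma in (6, 8):
        table[("5GY", f"4/{chroma}")] = 7
    for value, score in ((5, 6), (6, 5), (7, 4)):
        for chroma in (4, 6, 8, 10):
            table[("5GY", f"{value}/{chroma}")] = score
    for value, score in ((7, 3), (8, 2)):
        for chroma in (4, 6, 8):
            table[("2.5GY", f"{value}/{chroma}")] = score
    return table


#: Munsell chart (page, value/chroma) -> visual quality score 1..9.
#: The 2.5Y and 5Y pages map to 1 (yellow, plant death) for all colors.
MUNSELL_SCORES = _munsell_table()

_YELLOW_PAGES = ("2.5Y", "5Y")


def munsell_score(page: str, value_chroma: str | None = None) -> int:
    """Visual color-quality score (1-9) for a Munsell page + value/chroma."""
    page = str(page).strip()
    if page in _YELLOW_PAGES:
        return 1
    key = (page, str(value_chroma).strip())
    if key not in MUNSELL_SCORES:
        pages = sorted({p for p, _ in MUNSELL_SCORES} | set(_YELLOW_PAGES))
        raise ValidationError(
            f"unresolved Munsell code {key}; valid pages: {pages} "
            f"(2.5Y/5Y accept any value/chroma)"
        )
    return MUNSELL_SCORES[key]


def seasonal_color_mean(scores: Sequence[float], decimals: int = 1):
    """Seasonal color quality: unweighted mean of the ordered scores.

    ``scores`` is [initial (pre-stress, late March), April, May, June, July].
    Returns (full-precision mean, half-up rounded mean).
    """
    scores = list(scores)
    if not scores:
        raise ValidationError("no color scores supplied")
    bad = [s for s in scores if not 1 <= s <= 9]
    if bad:
        raise ValidationError(f"color scores outside [1, 9]: {bad}")
    mean = sum(float(s) for s in scores) / len(scores)
    return mean, round_half_up(mean, decimals)


def water_use_efficiency(seed_yield: float, water_total: float) -> float:
    """WUE (g m^-2 mm^-1) = seed yield / total water consumed."""
    if water_total <= 0:
        raise ValidationError(f"water_total {water_total} mm must be positive")
    if seed_yield < 0:
        raise ValidationError(f"seed_yield {seed_yield} must be >= 0")
    return seed_yield / water_total


def percent_reduction(reference: float, reduced: float, decimals: int | None = None) -> float:
    """Percent reduction 100*(reference - reduced)/reference.

    ``decimals`` optionally rounds half-up at the precision of the report
    being compared against.
    """
    if reference <= 0:
        raise ValidationError(f"reference {reference} must be positive")
    pct = 100.0 * (reference - reduced) / reference
    return pct if decimals is None else round_half_up(pct, decimals)
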