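"""Shared ordinary-least-squares core and report rounding.

Both the non-stressed baseline calibration and the CWSI-trait relations use
the same simple-linear-regression estimator, so it lives here once.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import CalibrationError

__all__ = ["LinearFit", "fit_line", "round_half_up"]


@dataclass(frozen=True)
class LinearFit:
    """Simple linear regression y = slope*x + intercept."""

    slope: float
    intercept: float
    r2: float
    n: int
    p_value: float
    stderr: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_line(x, y, min_points: int = 3) -> LinearFit:
    """OLS fit of y on x.

    Raises
    ------
    CalibrationError
        If fewer than ``min_points`` observations are supplied or the
        predictor has no spread (degenerate design).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("x and y must be 1-D arrays of equal length")
    if x.size < min_points:
        raise CalibrationError(
            f"need at least {min_points} points for a fit, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise CalibrationError("degenerate predictor: all x values identical")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        n=int(x.size),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at ``decimals`` places, as printed reports do.

    The value is first quantized at 1e-6 (inputs are printed at <=3 decimals,
    so true means have <=6 meaningful decimals) to absorb binary float error
    before the half-up decision.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    d = Decimal(repr(float(value))).quantize(Decimal("1e-6"), ROUND_HALF_UP)
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, ROUND_HALF_UP))
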