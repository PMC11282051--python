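"""Trend summaries for entropy time series.

Three estimators mirror how demographers summarize the pace of change of an
inequality measure: an ordinary least-squares line, a continuous two-segment
(hinge) piecewise line with the breakpoint found by exhaustive search, and
the mean intrinsic rate of change ln(v2/v1)/(t2 - t1) -- the analogue of an
instantaneous growth rate, exact for exponential trajectories.  Percent-per-
year paces are intrinsic rates times 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = ["TrendFit", "fit_linear", "fit_piecewise", "intrinsic_rate", "trend_frame"]


@dataclass(frozen=True)
class TrendFit:
    """A fitted trend.

    slope_per_year is the single OLS slope; for piecewise fits,
    segment_slopes holds (before, after) the breakpoint year.
    """

    slope_per_year: float
    intercept: float
    r_squared: float
    breakpoint_year: int | None = None
    segment_slopes: tuple[float, float] | None = None


def _as_xy(years, values, min_points: int):
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValidationError("years and values must be matching 1-D sequences")
    if x.size < min_points:
        raise ValidationError(f"need at least {min_points} points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite input")
    order = np.argsort(x)
    return x[order], y[order]


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - fitted) ** 2))
    if sst == 0.0:
        return 1.0
    return max(0.0, 1.0 - sse / sst)


def fit_linear(years: Sequence[float], values: Sequence[float]) -> TrendFit:
    """Ordinary least-squares line through (year, value) points."""
    x, y = _as_xy(years, values, 3)
    if np.ptp(x) == 0:
        raise ValidationError("years are constant; no slope is identified")
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), y, rcond=None)
    fitted = coef[0] + coef[1] * x
    return TrendFit(
        slope_per_year=float(coef[1]),
        intercept=float(coef[0]),
        r_squared=_r_squared(y, fitted),
    )


def fit_piecewise(years: Sequence[float], values: Sequence[float]) -> TrendFit:
    """Continuous two-segment least squares with an estimated breakpoint.

    The breakpoint is searched exhaustively over interior observation years
    leaving at least 3 points on each side; ties in total SSE go to the
    earliest year.  The hinge parameterization
    y = b0 + b1 t + b2 max(t - tau, 0) nests the plain line (b2 = 0), so the
    piecewise SSE never exceeds the linear SSE.
    """
    x, y = _as_xy(years, values, 7)
    if np.ptp(x) == 0:
        raise ValidationError("years are constant; no slope is identified")
    n = x.size
    best = None
    for k in range(2, n - 3 + 1):  # point k belongs to both segments
        tau = x[k]
        hinge = np.maximum(x - tau, 0.0)
        design = np.column_stack([np.ones_like(x), x, hinge])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((y - design @ coef) ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, tau, coef)
    sse, tau, coef = best
    fitted = coef[0] + coef[1] * x + coef[2] * np.maximum(x - tau, 0.0)
    return TrendFit(
        slope_per_year=float(coef[1]),
        intercept=float(coef[0]),
        r_squared=_r_squared(y, fitted),
        breakpoint_year=int(round(tau)),
        segment_slopes=(float(coef[1]), float(coef[1] + coef[2])),
    )


def intrinsic_rate(v1: float, v2: float, t1: float, t2: float) -> float:
    """Mean intrinsic rate of change ln(v2/v1)/(t2 - t1), per year."""
    if v1 <= 0 or v2 <= 0:
        raise DomainError(f"values must be positive, got {v1}, {v2}")
    if t2 <= t1:
        raise DomainError(f"t2 must exceed t1, got {t1}, {t2}")
    return float(np.log(v2 / v1) / (t2 - t1))


def trend_frame(rows: Sequence[tuple[str, str, TrendFit]]) -> pd.DataFrame:
    """Summary table of fits: (measure, population, fit) triples."""
    return pd.DataFrame(
        [
            {
                "measure": measure,
                "population": pop,
                "slope_per_year": f.slope_per_year,
                "slope_before": None if f.segment_slopes is None else f.segment_slopes[0],
                "slope_after": None if f.segment_slopes is None else f.segment_slopes[1],
                "breakpoint_year": f.breakpoint_year,
                "r_squared": f.r_squared,
            }
            for measure, pop, f in rows
        ]
    )
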