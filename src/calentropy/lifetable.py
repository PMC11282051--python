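"""Life-table summaries: life expectancy, e-dagger, and Keyfitz-Leser entropy.

The entropy of a life table,

    H = e_dagger / e_0 = -( integral l(x) ln l(x) dx ) / ( integral l(x) dx ),

is a relative measure of lifespan inequality: 0 when all deaths fall at a
single age, 1 when the hazard is the same at every age (exponential
survival).  It can exceed 1 under extreme infant mortality; such values are
flagged with a warning, never clamped.

Survival is built from single-year hazards with a piecewise-constant hazard
inside each age interval, l(x+s) = l(x) exp(-m(x) s), and both integrals use
the trapezoidal rule on the (optionally refined) grid.  Beyond the last
supplied age the terminal hazard is extended until survival falls below 1e-12
(capped 150 years past the last age; any remaining mass is recorded, not
integrated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .errors import CoverageError, DomainError
from .mortality_surface import MortalitySurface, SurvivalCurve

__all__ = [
    "LifetableSummary",
    "EntropyRangeWarning",
    "survival_from_hazard",
    "life_expectancy",
    "e_dagger",
    "entropy",
    "period_summary",
    "cohort_summary",
    "lifetable_frame",
    "write_hmd_lifetable",
]

LX_FLOOR = 1e-12
CLOSURE_CAP_YEARS = 150.0


class EntropyRangeWarning(UserWarning):
    """Entropy outside [0, 1]; possible under extreme infant mortality."""


@dataclass(frozen=True)
class LifetableSummary:
    """Scalar summaries of one survival curve.

    e0 : mean years of life; edagger : years of remaining life expectancy
    lost per death (absolute lifespan variation); entropy : e-dagger / e0,
    dimensionless; omega : top age of the integration grid.
    """

    e0: float
    edagger: float
    entropy: float
    omega: float


def _substeps(step: float) -> int:
    if step <= 0 or step > 1:
        raise DomainError(f"step must be in (0, 1], got {step}")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise DomainError(f"step {step} does not divide one year evenly")
    return n


def survival_from_hazard(
    hazard: np.ndarray,
    step: float = 1.0,
    close: bool = True,
    kind: str = "period",
    label: str = "",
) -> SurvivalCurve:
    """Build a survival curve from single-year hazards.

    Piecewise-constant hazard in each interval; with ``close`` the last
    hazard is extended until survival < 1e-12 (no extension when the terminal
    hazard is zero).
    """
    hazard = np.asarray(hazard, dtype=float)
    if hazard.ndim != 1 or hazard.size == 0:
        raise DomainError("hazard must be a non-empty 1-D vector")
    if not np.all(np.isfinite(hazard)):
        raise DomainError("hazard contains non-finite values")
    if np.any(hazard < 0):
        raise DomainError("hazard must be >= 0")
    nsub = _substeps(step)
    dense = np.repeat(hazard, nsub)

    if close and hazard[-1] > 0:
        tail_surv = float(np.exp(-np.sum(hazard)))
        if tail_surv > LX_FLOOR:
            extra_years = min(
                np.log(tail_surv / LX_FLOOR) / hazard[-1], CLOSURE_CAP_YEARS
            )
            n_extra = int(np.ceil(extra_years / step))
            dense = np.concatenate([dense, np.full(n_extra, hazard[-1])])

    cumhaz = np.concatenate([[0.0], np.cumsum(dense * step)])
    lx = np.exp(-cumhaz)
    ages = np.arange(lx.size) * step
    return SurvivalCurve(ages=ages, lx=lx, kind=kind, label=label)


def life_expectancy(curve: SurvivalCurve) -> float:
    """Trapezoidal integral of l(x) over the age grid (years)."""
    return float(np.trapezoid(curve.lx, curve.ages))


def e_dagger(curve: SurvivalCurve) -> float:
    """Trapezoidal integral of -l(x) ln l(x); 0*ln 0 and 1*ln 1 are 0."""
    lx = np.clip(curve.lx, 0.0, 1.0)
    return float(np.trapezoid(-xlogy(lx, lx), curve.ages))


def entropy(curve: SurvivalCurve) -> LifetableSummary:
    """e0, e-dagger and their ratio for one survival curve."""
    e0 = life_expectancy(curve)
    ed = e_dagger(curve)
    if e0 <= 0:
        raise DomainError("degenerate survival curve: e0 <= 0")
    h = ed / e0
    if h > 1 + 1e-9 or h < -1e-12:
        warnings.warn(
            f"life table entropy {h:.6f} outside [0, 1]", EntropyRangeWarning
        )
    return LifetableSummary(e0=e0, edagger=ed, entropy=h, omega=float(curve.ages[-1]))


def period_summary(surface: MortalitySurface, year: int, step: float = 1.0) -> LifetableSummary:
    """Entropy summary of the period life table for one calendar year."""
    curve = survival_from_hazard(
        surface.period_column(year), step=step, kind="period", label=str(year)
    )
    return entropy(curve)


def cohort_summary(surface: MortalitySurface, birth_year: int, step: float = 1.0) -> LifetableSummary:
    """Entropy summary for a birth cohort followed to the surface's top age.

    Requires the full diagonal up to the top age; the terminal hazard closes
    the table beyond it.
    """
    top = surface.age_max
    if birth_year + top > surface.years[-1] or birth_year < surface.years[0]:
        raise CoverageError(
            f"cohort {birth_year} is not observed to age {top} "
            f"(surface years {surface.years[0]}..{surface.years[-1]})"
        )
    curve = survival_from_hazard(
        surface.cohort_diagonal(birth_year, top),
        step=step,
        kind="cohort",
        label=str(birth_year),
    )
    return entropy(curve)


# -- HMD-style life-table output --------------------------------------------


def lifetable_frame(hazard: np.ndarray, year: int | None = None, radix: float = 100_000.0) -> pd.DataFrame:
    """Single-year life table (columns Year Age mx qx ax lx dx Lx Tx ex).

    Uses the package's piecewise-constant-hazard convention; lx is scaled to
    the radix for output only.
    """
    m = np.asarray(hazard, dtype=float)
    if np.any(m < 0):
        raise DomainError("hazard must be >= 0")
    n = m.size
    qx = -np.expm1(-m)
    lx = np.concatenate([[1.0], np.exp(-np.cumsum(m))])
    dx = lx[:-1] - lx[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        Lx = np.where(m > 0, dx / m, lx[:-1])
        ax = np.where(dx > 0, (Lx - lx[1:]) / dx, 0.5)
    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx[:-1] > 0, Tx / lx[:-1], 0.0)
    out = pd.DataFrame(
        {
            "Year": year if year is not None else "-",
            "Age": np.arange(n),
            "mx": m,
            "qx": qx,
            "ax": ax,
            "lx": np.round(lx[:-1] * radix).astype(int),
            "dx": np.round(dx * radix).astype(int),
            "Lx": np.round(Lx * radix).astype(int),
            "Tx": np.round(Tx * radix).astype(int),
            "ex": ex,
        }
    )
    return out


def write_hmd_lifetable(frame: pd.DataFrame, path) -> None:
    """Write a life table in the HMD period life-table column layout."""
    with open(path, "w") as fh:
        fh.write("Life table (period 1x1), radix 100000\n\n")
        fh.write(
            f"{'Year':>6} {'Age':>4} {'mx':>9} {'qx':>9} {'ax':>5} "
            f"{'lx':>7} {'dx':>7} {'Lx':>7} {'Tx':>8} {'ex':>7}\n"
        )
        for _, r in frame.iterrows():
            fh.write(
                f"{r.Year!s:>6} {int(r.Age):>4} {r.mx:>9.5f} {min(r.qx, 1.0):>9.5f} "
                f"{r.ax:>5.2f} {int(r.lx):>7} {int(r.dx):>7} {int(r.Lx):>7} "
                f"{int(r.Tx):>8} {r.ex:>7.2f}\n"
            )
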