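"""Cross-sectional average length of life (CAL) and its entropy.

CAL(t) integrates, over age x, the survival to age x of the cohort born in
year t - x:

    CAL(t)     =  integral_0^omega  l_c(x, t - x) dx
    CAL+(t)    = -integral_0^omega  l_c(x, t - x) ln l_c(x, t - x) dx
    H_CAL(t)   =  CAL+(t) / CAL(t)

so every cohort alive at time t contributes its own survival history.  The
integrand is assembled age by age from distinct cohorts: each cohort's
survival to its exact integer age is computed independently from its Lexis
diagonal, then sampled once.  The spliced curve need not be monotone.

H_CAL shares the entropy limits: 1 when rates are equal across all ages and
cohorts, 0 when every cohort's deaths are concentrated at one age.  For a
time-invariant surface (CAL, CAL+, H_CAL) collapse exactly to the period
(e0, e-dagger, H).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError
from .lifetable import (
    CLOSURE_CAP_YEARS,
    LX_FLOOR,
    _substeps,
    e_dagger,
    life_expectancy,
)
from .mortality_surface import MortalitySurface, SurvivalCurve

__all__ = [
    "CALResult",
    "cal_survival_vector",
    "cal",
    "cal_dagger",
    "cal_entropy",
    "cal_series",
    "write_cal_csv",
    "default_omega",
]

DEFAULT_OMEGA = 110


@dataclass(frozen=True)
class CALResult:
    """CAL, CAL-dagger and their ratio for one population-year."""

    year: int
    cal: float
    cal_dagger: float
    h_cal: float
    n_cohorts: int

    def __post_init__(self) -> None:
        if self.cal <= 0:
            raise DomainError(f"CAL must be positive, got {self.cal}")
        if self.cal_dagger < 0:
            raise DomainError(f"CAL-dagger must be >= 0, got {self.cal_dagger}")
        if abs(self.h_cal - self.cal_dagger / self.cal) > 1e-12:
            raise DomainError("h_cal must equal cal_dagger / cal")


def default_omega(surface: MortalitySurface, omega: int | None) -> int:
    return min(DEFAULT_OMEGA, surface.age_max) if omega is None else int(omega)


def cal_survival_vector(
    surface: MortalitySurface,
    year: int,
    omega: int | None = None,
    step: float = 1.0,
    close: bool = True,
) -> SurvivalCurve:
    """The spliced cohort survival curve v(x) = l_c(x, year - x), x = 0..omega.

    Integer-age nodes come from the exact cumulative diagonal hazard of the
    cohort aged x at time ``year``.  With ``step`` < 1, the curve inside
    [x, x+1) decays with m(x, year) -- the hazard that cohort experiences
    during ``year`` -- which reduces exactly to the refined period curve when
    the surface is time-invariant.  Beyond omega the oldest cohort's current
    hazard closes the tail as in the life-table construction.
    """
    omega = default_omega(surface, omega)
    if omega < 0:
        raise DomainError("omega must be >= 0")
    report = surface.cal_coverage_check(year, omega)
    if not report.ok:
        raise CoverageError(f"CAL({year}) not computable: {report.message()}")

    y0 = int(surface.years[0])
    # cumulative hazard to exact age x of the cohort born year - x
    cum = np.empty(omega + 1)
    cum[0] = 0.0
    for x in range(1, omega + 1):
        a = np.arange(x)
        cum[x] = float(np.sum(surface.rates[a, (year - x - y0) + a]))
    v_int = np.exp(-cum)

    nsub = _substeps(step)
    # within-year hazards at time `year` for the cohort occupying [x, x+1)
    col = surface.period_column(year)
    m_now = col[np.minimum(np.arange(omega), surface.age_max)] if omega > 0 else np.empty(0)

    n = omega * nsub + 1
    ages = np.arange(n) * step
    v = np.empty(n)
    v[::nsub] = v_int
    if nsub > 1:
        for x in range(omega):
            s = np.arange(1, nsub) * step
            v[x * nsub + 1 : (x + 1) * nsub] = v_int[x] * np.exp(-m_now[x] * s)

    if close:
        h_term = float(col[min(omega, surface.age_max)])
        tail = v_int[-1]
        if h_term > 0 and tail > LX_FLOOR:
            extra_years = min(np.log(tail / LX_FLOOR) / h_term, CLOSURE_CAP_YEARS)
            n_extra = int(np.ceil(extra_years / step))
            s = np.arange(1, n_extra + 1) * step
            ages = np.concatenate([ages, omega + s])
            v = np.concatenate([v, tail * np.exp(-h_term * s)])

    return SurvivalCurve(ages=ages, lx=v, kind="cal-diagonal", label=str(year))


def cal(
    surface: MortalitySurface,
    year: int,
    omega: int | None = None,
    step: float = 1.0,
) -> float:
    """CAL(t): trapezoidal integral of the spliced cohort survival (years)."""
    return life_expectancy(cal_survival_vector(surface, year, omega, step))


def cal_dagger(
    surface: MortalitySurface,
    year: int,
    omega: int | None = None,
    step: float = 1.0,
) -> float:
    """CAL-dagger(t): -integral v ln v with 0*ln 0 = 0 (years)."""
    return e_dagger(cal_survival_vector(surface, year, omega, step))


def cal_entropy(
    surface: MortalitySurface,
    year: int,
    omega: int | None = None,
    step: float = 1.0,
) -> CALResult:
    """CAL, CAL-dagger and H_CAL = CAL-dagger / CAL for one year."""
    omega = default_omega(surface, omega)
    curve = cal_survival_vector(surface, year, omega, step)
    c = life_expectancy(curve)
    cd = e_dagger(curve)
    if c <= 0:
        raise DomainError(f"degenerate CAL({year}) = {c}")
    return CALResult(
        year=int(year), cal=c, cal_dagger=cd, h_cal=cd / c, n_cohorts=omega + 1
    )


def cal_series(
    surface: MortalitySurface,
    years: Iterable[int],
    omega: int | None = None,
    step: float = 1.0,
    partial: bool = False,
) -> list[CALResult]:
    """CALResult per requested year, in year order.

    By default the first year without full cohort coverage raises; with
    ``partial`` uncovered years are skipped instead of failing.
    """
    out: list[CALResult] = []
    for year in sorted(years):
        try:
            out.append(cal_entropy(surface, year, omega, step))
        except CoverageError:
            if not partial:
                raise
    return out


def write_cal_csv(results: Sequence[CALResult], path: str | Path) -> None:
    """CSV with columns year, cal, cal_dagger, h_cal, n_cohorts."""
    pd.DataFrame(
        [
            {
                "year": r.year,
                "cal": r.cal,
                "cal_dagger": r.cal_dagger,
                "h_cal": r.h_cal,
                "n_cohorts": r.n_cohorts,
            }
            for r in results
        ]
    ).to_csv(path, index=False, float_format="%.12g")
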