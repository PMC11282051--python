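"""Synthetic Lexis surfaces with known structure.

The generator emulates a multi-decade mortality surface for a low-mortality
population: a Gompertz-Makeham age profile (a e^{bx} + c), a proportional
period improvement e^{-rho (t - t0)}, optional multiplicative cohort effects,
one-year period shocks (epidemics, wars), and optional mean-one lognormal
rate noise.  Every measure in the package is therefore testable without any
data download, and the degenerate fixtures behind the analytic limits
(constant hazard, knife-edge mortality) are one call away.

``divergence_pair`` builds two surfaces that, by construction, drift apart in
only one of the two components of CAL-entropy: either the dispersion of the
death distribution diverges while CAL is pinned (variation_only), or the mean
shifts while CAL-dagger is pinned.  The pinning is enforced by per-column
calibration and verified internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .cal import cal_entropy, cal_survival_vector, default_omega
from .errors import ConstructionError, ValidationError
from .lifetable import e_dagger, life_expectancy
from .mortality_surface import MortalitySurface

__all__ = [
    "ScenarioSpec",
    "build_surface",
    "knife_edge_surface",
    "divergence_pair",
    "DEFAULT_SCENARIO",
]

LETHAL_HAZARD = 1.0e3  # exp(-1000) underflows to exactly 0.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic mortality surface.

    Defaults are the package's standard test scenario: a Gompertz-Makeham
    schedule typical of a 20th-century low-mortality population with a 1.2%
    annual proportional improvement, ages 0..110 and years 1870..2020.
    """

    makeham_a: float = 3.0e-5   # Gompertz level, per year
    makeham_b: float = 0.095    # Gompertz slope, per year of age
    makeham_c: float = 2.0e-4   # age-independent background hazard, per year
    improvement_rho: float = 0.012  # proportional hazard decline per year
    cohort_effect: Mapping[int, float] | Callable[[int], float] | None = None
    shocks: tuple[tuple[int, float], ...] = ()
    age_max: int = 110
    year_start: int = 1870
    year_end: int = 2020
    seed: int = 20240725
    noise_sd: float = 0.0       # lognormal sd of multiplicative rate noise
    label: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("makeham_a", "makeham_b", "makeham_c", "improvement_rho",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.makeham_a == 0 and self.makeham_c == 0:
            raise ValidationError("hazard is identically zero: set makeham_a or makeham_c")
        if self.age_max < 0 or self.year_end < self.year_start:
            raise ValidationError("invalid age or year range")
        for year, mult in self.shocks:
            if mult <= 0:
                raise ValidationError(f"shock multiplier at {year} must be > 0")

    def _cohort_factor(self, cohorts: np.ndarray) -> np.ndarray:
        if self.cohort_effect is None:
            return np.ones_like(cohorts, dtype=float)
        if callable(self.cohort_effect):
            out = np.array([float(self.cohort_effect(int(c))) for c in cohorts])
        else:
            out = np.array([float(self.cohort_effect.get(int(c), 1.0)) for c in cohorts])
        if np.any(out <= 0):
            raise ValidationError("cohort_effect factors must be > 0")
        return out


def build_surface(spec: ScenarioSpec) -> MortalitySurface:
    """m(x,t) = (a e^{bx} + c) e^{-rho (t-t0)} cohort(t-x) shock(t) noise(x,t)."""
    ages = np.arange(spec.age_max + 1)
    years = np.arange(spec.year_start, spec.year_end + 1)
    base = spec.makeham_a * np.exp(spec.makeham_b * ages) + spec.makeham_c
    improv = np.exp(-spec.improvement_rho * (years - years[0]))
    rates = np.outer(base, improv)

    shock = np.ones(years.size)
    for year, mult in spec.shocks:
        if year < years[0] or year > years[-1]:
            raise ValidationError(f"shock year {year} outside {years[0]}..{years[-1]}")
        shock[year - years[0]] *= mult
    rates *= shock[None, :]

    if spec.cohort_effect is not None:
        cohorts = years[None, :] - ages[:, None]
        uniq = np.arange(cohorts.min(), cohorts.max() + 1)
        factor = spec._cohort_factor(uniq)
        rates *= factor[cohorts - uniq[0]]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd
        rates *= rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=rates.shape)

    return MortalitySurface(
        ages=ages, years=years, rates=rates, population_label=spec.label
    )


DEFAULT_SCENARIO = ScenarioSpec()


def knife_edge_surface(
    death_age: int,
    years: Sequence[int] | range,
    age_max: int | None = None,
) -> MortalitySurface:
    """Everyone survives to ``death_age`` and dies within that year, every year.

    The hazard is 0 below the death age and numerically infinite (survival
    through the interval underflows to 0) at and above it.
    """
    years = np.asarray(sorted(years))
    age_max = death_age if age_max is None else age_max
    if not 0 <= death_age <= age_max:
        raise ValidationError("death_age must lie within the age range")
    ages = np.arange(age_max + 1)
    rates = np.zeros((ages.size, years.size))
    rates[death_age:, :] = LETHAL_HAZARD
    return MortalitySurface(
        ages=ages, years=years, rates=rates,
        population_label=f"knife-edge@{death_age}",
    )


# -- divergence pairs --------------------------------------------------------


def _cal_measures(rates: np.ndarray, template: MortalitySurface, year: int,
                  omega: int) -> tuple[float, float]:
    s = MortalitySurface(ages=template.ages, years=template.years, rates=rates,
                         population_label=template.population_label)
    curve = cal_survival_vector(s, year, omega)
    return life_expectancy(curve), e_dagger(curve)


def divergence_pair(
    spec: ScenarioSpec | None = None,
    variation_only: bool = True,
    omega: int | None = None,
    max_tilt: float = 0.6,
    pivot_age: float = 70.0,
    preserve_tol: float = 0.05,
) -> tuple[MortalitySurface, MortalitySurface]:
    """Two surfaces (A, B) that differ, by construction, in one component only.

    variation_only=True: B's hazards acquire a growing age tilt
    exp(gamma(t) (x - pivot)/age_max) that spreads or compresses the death
    distribution, and a per-column scalar is calibrated (root-finding) so
    that CAL_B(t) tracks CAL_A(t) exactly at every covered year -- only the
    lifespan-variation component CAL-dagger diverges.

    variation_only=False: B's log-hazard schedule is shifted up the age axis
    by a growing delta(t) (a pure location shift of the death distribution),
    which moves CAL while leaving CAL-dagger nearly unchanged; the
    preservation is verified against ``preserve_tol`` (years) and a
    ConstructionError is raised if the construction misses it.

    The default tilt strength targets a final relative divergence of a few
    percent in the moving component.
    """
    spec = DEFAULT_SCENARIO if spec is None else spec
    if spec.noise_sd > 0:
        raise ValidationError("divergence_pair requires a noise-free base spec")
    a_surface = build_surface(spec)
    omega = default_omega(a_surface, omega)
    years = a_surface.years
    first = int(years[0]) + omega  # first year with full CAL coverage
    last = int(years[-1])
    if first >= last:
        raise ValidationError(
            f"surface too short: first covered CAL year {first} is not "
            f"before the last year {last}"
        )

    ages = a_surface.ages.astype(float)
    b_rates = a_surface.rates.copy()
    ramp = lambda t: (t - first + 1) / (last - first)  # 0 -> 1 over covered span

    if variation_only:
        tilt_profile = (ages - pivot_age) / max(spec.age_max, 1)
        # columns `first`..`last-1` drive CAL(first+1)..CAL(last); calibrate each
        for t in range(first, last):
            j = t - int(years[0])
            tilted = a_surface.rates[:, j] * np.exp(max_tilt * ramp(t) * tilt_profile)
            target, _ = _cal_measures(a_surface.rates, a_surface, t + 1, omega)

            def mismatch(s: float) -> float:
                b_rates[:, j] = s * tilted
                got, _ = _cal_measures(b_rates, a_surface, t + 1, omega)
                return got - target

            try:
                s_star = brentq(mismatch, 0.2, 5.0, xtol=1e-12, rtol=1e-14)
            except ValueError as err:
                raise ConstructionError(
                    f"CAL calibration bracket failed at year {t}: {err}"
                ) from None
            b_rates[:, j] = s_star * tilted
        moving, pinned = "cal_dagger", "cal"
    else:
        # age-shift of the log-hazard schedule: a location shift of deaths
        for t in range(first, last):
            j = t - int(years[0])
            delta = max_tilt * ramp(t)  # years of shift
            logm = np.log(a_surface.rates[:, j])
            b_rates[:, j] = np.exp(np.interp(ages - delta, ages, logm))
        moving, pinned = "cal", "cal_dagger"

    b_surface = MortalitySurface(
        ages=a_surface.ages, years=years, rates=b_rates,
        population_label=f"{spec.label}-divergent",
    )

    # internal verification: the pinned measure must track within tolerance
    for t in range(first, last + 1):
        ca, da = _cal_measures(a_surface.rates, a_surface, t, omega)
        cb, db = _cal_measures(b_rates, a_surface, t, omega)
        kept = abs((ca - cb) if pinned == "cal" else (da - db))
        if kept > preserve_tol:
            raise ConstructionError(
                f"divergence_pair failed to preserve {pinned} at year {t}: "
                f"|difference| = {kept:.4f} > {preserve_tol}"
            )
    return a_surface, b_surface
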