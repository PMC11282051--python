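"""Age x calendar-year mortality surfaces (Lexis surfaces).

A :class:`MortalitySurface` holds age-specific death rates m(x, t) on a
rectangular grid of single-year ages and consecutive calendar years.  Ages and
years are integer labels for the intervals [x, x+1) and [t, t+1).  The cohort
convention used throughout the package: the cohort born in year c experiences
hazard m(a, c + a) during age a -- one Lexis cell per age, no triangle
splitting (single-year rates do not resolve triangles).

Readers accept the Human Mortality Database 1x1 death-rate text layout and a
long-format CSV (``year,age,mx``).  Missing data are rejected, never imputed:
a gap in any cohort's history would silently contaminate every later
cross-sectional measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, ParseError, ValidationError

__all__ = [
    "MortalitySurface",
    "SurvivalCurve",
    "CoverageReport",
    "read_hmd_rates",
    "read_csv_surface",
    "write_csv_surface",
    "write_hmd_rates",
]

_SEXES = ("female", "male", "total")


@dataclass(frozen=True)
class MortalitySurface:
    """Rectangular grid of hazards m(x, t) over single-year ages and years.

    Parameters
    ----------
    ages
        Integer age grid, starting at 0, consecutive.
    years
        Integer calendar-year grid, consecutive.
    rates
        Matrix of shape ``(len(ages), len(years))``; finite, >= 0.
    population_label, sex
        Provenance metadata; ``sex`` is one of female/male/total.
    """

    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray
    population_label: str = ""
    sex: str = "total"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        years = np.asarray(self.years, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if ages.ndim != 1 or years.ndim != 1:
            raise ValidationError("ages and years must be 1-D")
        if ages.size == 0 or years.size == 0:
            raise ValidationError("empty age or year grid")
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise ValidationError("ages must start at 0 and be consecutive single years")
        if np.any(np.diff(years) != 1):
            raise ValidationError("years must be consecutive")
        if rates.shape != (ages.size, years.size):
            raise ValidationError(
                f"rates shape {rates.shape} does not match "
                f"(|ages|, |years|) = {(ages.size, years.size)}"
            )
        if not np.all(np.isfinite(rates)):
            bad = np.argwhere(~np.isfinite(rates))[0]
            raise ValidationError(
                f"non-finite rate at age {ages[bad[0]]}, year {years[bad[1]]}"
            )
        if np.any(rates < 0):
            bad = np.argwhere(rates < 0)[0]
            raise ValidationError(
                f"negative rate at age {ages[bad[0]]}, year {years[bad[1]]}"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def _year_index(self, year: int) -> int:
        if year < self.years[0] or year > self.years[-1]:
            raise CoverageError(
                f"year {year} outside surface range "
                f"{self.years[0]}..{self.years[-1]}"
            )
        return int(year - self.years[0])

    def period_column(self, year: int) -> np.ndarray:
        """Hazards m(., year) over all ages -- the vertical of the Lexis plane."""
        return self.rates[:, self._year_index(year)].copy()

    def cohort_diagonal(self, birth_year: int, max_age: int) -> np.ndarray:
        """Hazards m(a, birth_year + a) for a = 0..max_age -- the Lexis diagonal."""
        if max_age < 0:
            raise ValidationError("max_age must be >= 0")
        if max_age > self.age_max:
            raise CoverageError(
                f"cohort {birth_year}: age {self.age_max + 1} exceeds the surface "
                f"top age {self.age_max}"
            )
        if birth_year < self.years[0]:
            first_a = 0  # years are contiguous, so the first cell is already off-surface
        elif birth_year + max_age > self.years[-1]:
            first_a = int(self.years[-1]) - birth_year + 1
        else:
            first_a = None
        if first_a is not None:
            raise CoverageError(
                f"cohort {birth_year}: cell (age {first_a}, year "
                f"{birth_year + first_a}) outside surface years "
                f"{self.years[0]}..{self.years[-1]}"
            )
        a = np.arange(max_age + 1)
        return self.rates[a, birth_year - self.years[0] + a].copy()

    def cal_coverage_check(self, year: int, omega: int) -> "CoverageReport":
        """Can CAL(year) be assembled from cohorts born year-omega .. year?

        Each cohort born c must have a complete diagonal up to the age it
        attains by ``year`` (cells at ages 0..year-c-1, i.e. years c..year-1),
        and ``year`` itself must lie on the surface.
        """
        missing: list[int] = []
        notes: list[str] = []
        if year < self.years[0] or year > self.years[-1]:
            notes.append(f"year {year} not on the surface")
            return CoverageReport(False, missing, notes)
        for c in range(year - omega, year + 1):
            attained = year - c  # age attained by `year`; needs ages 0..attained-1
            if attained == 0:
                continue
            if c < self.years[0]:
                missing.append(c)
            elif attained - 1 > self.age_max:
                missing.append(c)
                notes.append(
                    f"cohort {c} needs ages up to {attained - 1} "
                    f"but surface tops out at {self.age_max}"
                )
        ok = not missing
        if missing:
            notes.insert(
                0,
                f"{len(missing)} cohort(s) lack complete diagonals for "
                f"CAL({year}) with omega={omega}: born "
                f"{missing[0]}..{missing[-1]}",
            )
        return CoverageReport(ok, missing, notes)


@dataclass(frozen=True)
class CoverageReport:
    ok: bool
    missing_cohorts: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok

    def message(self) -> str:
        return "; ".join(self.notes) if self.notes else "coverage complete"


@dataclass(frozen=True)
class SurvivalCurve:
    """A survival function l(x) on an age grid, radix 1.

    ``kind`` is one of period / cohort / cal-diagonal.  Period and cohort
    curves must be non-increasing; a cal-diagonal splices together survival
    probabilities of *different* cohorts sampled each at one age, so only
    l(0) = 1 and 0 <= l <= 1 are enforced there.
    """

    ages: np.ndarray
    lx: np.ndarray
    kind: str = "period"
    label: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        lx = np.asarray(self.lx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lx", lx)
        if self.kind not in ("period", "cohort", "cal-diagonal"):
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        if ages.ndim != 1 or lx.shape != ages.shape or ages.size == 0:
            raise ValidationError("ages and lx must be matching 1-D arrays")
        if ages[0] != 0.0 or np.any(np.diff(ages) <= 0):
            raise ValidationError("age grid must start at 0 and strictly increase")
        if abs(lx[0] - 1.0) > 1e-12:
            raise ValidationError(f"lx[0] must be 1 (radix 1), got {lx[0]}")
        if np.any(lx < -1e-15) or np.any(lx > 1 + 1e-12):
            raise ValidationError("lx must lie in [0, 1]")
        if self.kind != "cal-diagonal" and np.any(np.diff(lx) > 1e-12):
            raise ValidationError(f"{self.kind} survival curve must be non-increasing")


# -- Human Mortality Database 1x1 rates layout ------------------------------

_HMD_COLS = ("Year", "Age", "Female", "Male", "Total")


def read_hmd_rates(path: str | Path, sex: str = "total") -> MortalitySurface:
    """Read an HMD ``Mx_1x1``-layout text file for one sex.

    Layout: a title line and a blank line, then a header row
    ``Year Age Female Male Total`` and whitespace-separated data rows.  Age
    runs "0".."109", "110+"; "." marks a missing rate.  The open age class is
    kept as the top age with its rate; missing cells raise, listing every
    (year, age) affected.
    """
    if sex not in _SEXES:
        raise ValidationError(f"sex must be one of {_SEXES}, got {sex!r}")
    path = Path(path)
    lines = path.read_text().splitlines()

    header_i = None
    for i, line in enumerate(lines[:6]):
        parts = line.split()
        if parts[:2] == ["Year", "Age"]:
            header_i = i
            break
    if header_i is None:
        raise ParseError(f"{path.name}: no 'Year Age ...' header in the first lines")
    header = lines[header_i].split()
    if tuple(header[:5]) != _HMD_COLS:
        raise ParseError(
            f"{path.name}, line {header_i + 1}: expected columns "
            f"{' '.join(_HMD_COLS)}, got {' '.join(header)}"
        )
    col = {"female": 2, "male": 3, "total": 4}[sex]

    values: dict[tuple[int, int], float] = {}
    missing: list[tuple[int, int]] = []
    top_age = 0
    for lineno, line in enumerate(lines[header_i + 1 :], start=header_i + 2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ParseError(
                f"{path.name}, line {lineno}: expected 5 columns, got {len(parts)}"
            )
        try:
            year = int(parts[0])
        except ValueError:
            raise ParseError(f"{path.name}, line {lineno}: bad Year {parts[0]!r}")
        age_s = parts[1]
        try:
            age = int(age_s.rstrip("+")) if age_s.endswith("+") else int(age_s)
        except ValueError:
            raise ParseError(f"{path.name}, line {lineno}: bad Age {age_s!r}")
        raw = parts[col]
        if raw == ".":
            missing.append((year, age))
            continue
        try:
            mx = float(raw)
        except ValueError:
            raise ParseError(
                f"{path.name}, line {lineno}: bad {sex} rate {raw!r}"
            )
        if (year, age) in values:
            raise ParseError(
                f"{path.name}, line {lineno}: duplicate cell year {year}, age {age}"
            )
        values[(year, age)] = mx
        top_age = max(top_age, age)

    if missing:
        listed = ", ".join(f"({y}, {a})" for y, a in missing[:20])
        more = "" if len(missing) <= 20 else f" and {len(missing) - 20} more"
        raise ValidationError(
            f"{path.name}: missing '{sex}' rates at (year, age): {listed}{more}"
        )
    if not values:
        raise ParseError(f"{path.name}: no data rows")

    years = sorted({y for y, _ in values})
    if years != list(range(years[0], years[-1] + 1)):
        raise ValidationError(f"{path.name}: years are not contiguous: {years}")
    ages = list(range(top_age + 1))
    rates = np.empty((len(ages), len(years)))
    holes = [
        (y, a) for y in years for a in ages if (y, a) not in values
    ]
    if holes:
        listed = ", ".join(f"({y}, {a})" for y, a in holes[:20])
        raise ValidationError(f"{path.name}: absent cells at (year, age): {listed}")
    for (y, a), mx in values.items():
        rates[a, y - years[0]] = mx
    return MortalitySurface(
        ages=np.array(ages),
        years=np.array(years),
        rates=rates,
        population_label=path.stem,
        sex=sex,
    )


def write_hmd_rates(surface: MortalitySurface, path: str | Path, title: str | None = None) -> None:
    """Write a surface in the HMD 1x1 rates layout.

    The single surface's rates are written into the Female, Male and Total
    columns alike, so reading any sex back round-trips.
    """
    path = Path(path)
    title = title or f"{surface.population_label or 'synthetic'}, death rates (period 1x1)"
    out = [title, ""]
    out.append(f"{'Year':>6}{'Age':>13}{'Female':>15}{'Male':>15}{'Total':>15}")
    top = surface.age_max
    for j, year in enumerate(surface.years):
        for i, age in enumerate(surface.ages):
            age_s = f"{age}+" if age == top and top >= 110 else str(age)
            r = f"{surface.rates[i, j]:.8f}"
            out.append(f"{year:>6}{age_s:>13}{r:>15}{r:>15}{r:>15}")
    path.write_text("\n".join(out) + "\n")


# -- long CSV layout --------------------------------------------------------


def read_csv_surface(path: str | Path) -> MortalitySurface:
    """Read a long-format CSV with header ``year,age,mx`` into a surface."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"year", "age", "mx"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path.name}: header must contain columns year, age, mx "
            f"(got {list(df.columns)})"
        )
    if df[["year", "age"]].duplicated().any():
        dup = df[df[["year", "age"]].duplicated()].iloc[0]
        raise ValidationError(
            f"{path.name}: duplicate (year, age) pair ({int(dup.year)}, {int(dup.age)})"
        )
    if df["mx"].isna().any():
        row = df[df["mx"].isna()].iloc[0]
        raise ValidationError(
            f"{path.name}: missing mx at (year {int(row.year)}, age {int(row.age)})"
        )
    if (df["mx"] < 0).any():
        row = df[df["mx"] < 0].iloc[0]
        raise ValidationError(
            f"{path.name}: negative mx at (year {int(row.year)}, age {int(row.age)})"
        )
    wide = df.pivot(index="age", columns="year", values="mx").sort_index()
    if wide.isna().any().any():
        age, year = next(
            (a, y) for a in wide.index for y in wide.columns if pd.isna(wide.loc[a, y])
        )
        raise ValidationError(f"{path.name}: absent cell (year {year}, age {age})")
    return MortalitySurface(
        ages=wide.index.to_numpy(),
        years=wide.columns.to_numpy(),
        rates=wide.to_numpy(),
        population_label=path.stem,
    )


def write_csv_surface(surface: MortalitySurface, path: str | Path) -> None:
    """Write a surface as a long CSV (columns year, age, mx)."""
    years = np.repeat(surface.years, surface.ages.size)
    ages = np.tile(surface.ages, surface.years.size)
    mx = surface.rates.T.reshape(-1)
    pd.DataFrame({"year": years, "age": ages, "mx": mx}).to_csv(
        path, index=False, float_format="%.12g"
    )


# -- module-level aliases for the extraction operations ---------------------


def period_column(surface: MortalitySurface, year: int) -> np.ndarray:
    return surface.period_column(year)


def cohort_diagonal(surface: MortalitySurface, birth_year: int, max_age: int) -> np.ndarray:
    return surface.cohort_diagonal(birth_year, max_age)


def cal_coverage_check(surface: MortalitySurface, year: int, omega: int) -> CoverageReport:
    return surface.cal_coverage_check(year, omega)
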