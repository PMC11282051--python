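"""Decompositions of CAL-entropy gaps between a population and a benchmark.

Cross-population gap.  For population p and benchmark b at one year, with
R+ = ln(CAL+_p / CAL+_b) and R = ln(CAL_p / CAL_b), the gap
H_p - H_b splits into a lifespan-variation and a longevity contribution

    contrib_variation =  H~ * R+
    contrib_longevity = -H~ * R

where H~ is the logarithmic-mean entropy scale H~ = (H_p - H_b)/(R+ - R)
(falling back to the arithmetic mean when R+ - R vanishes).  Because the
relative "derivatives" of the continuous theory are realized as log-ratios,
the two contributions sum to the gap exactly -- no residual is folded in.

Change of the gap over time (differences of differences).  Writing
D = R+ - R, the gap is H~ D, and the exact discrete product rule
Delta(ab) = Delta(a) b_mid + a_mid Delta(b) splits the change between t-1
and t into

    term_benchmark = Delta(H~) * D_mid          (entropy-level change)
    term_variation =  H~_mid * Delta(R+)        (lifespan variation)
    term_longevity = -H~_mid * Delta(R)         (longevity)

with midpoint values averaging t-1 and t.  The residual is computed and
reported; with this scheme it is numerical roundoff only.

The benchmark is, by default, the unweighted arithmetic mean of the member
populations' entropy levels (with mean CAL and CAL+ carried along for the
log-ratios); an averaged-rates benchmark is available as a sensitivity mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cal import CALResult, cal_entropy
from .errors import DomainError, ValidationError
from .mortality_surface import MortalitySurface

__all__ = [
    "BenchmarkCAL",
    "GapDecomposition",
    "GapChangeDecomposition",
    "ShareSeries",
    "benchmark_average",
    "benchmark_from_surfaces",
    "gap_decompose",
    "gap_change_decompose",
    "component_shares",
    "crossover_detect",
    "gap_frame",
    "gap_change_frame",
]

_LOG_TOL = 1e-12


@dataclass(frozen=True)
class BenchmarkCAL:
    """CALResult-like benchmark; h_cal is a mean of entropies, so it need not
    equal cal_dagger / cal."""

    year: int
    cal: float
    cal_dagger: float
    h_cal: float
    n_cohorts: int
    n_populations: int
    mode: str = "mean-of-entropy"


@dataclass(frozen=True)
class GapDecomposition:
    """One year's CAL-entropy gap and its two exactly-additive contributions."""

    year: int
    population: str
    gap: float
    contrib_variation: float
    contrib_longevity: float


@dataclass(frozen=True)
class GapChangeDecomposition:
    """Change of the gap between year t-1 and t, split into three terms."""

    year_pair: tuple[int, int]
    population: str
    total_change: float
    term_benchmark: float
    term_variation: float
    term_longevity: float
    residual: float


@dataclass(frozen=True)
class ShareSeries:
    """Rolling-mean share of one component in the total absolute contribution."""

    component: str
    years: np.ndarray
    share: np.ndarray
    window: int


def benchmark_average(
    results: Sequence[CALResult], mode: str = "mean-of-entropy"
) -> BenchmarkCAL:
    """Benchmark from per-population CAL results at one year.

    The default takes unweighted arithmetic means of H_CAL, CAL and
    CAL-dagger across populations.  The averaged-rates sensitivity mode needs
    the surfaces themselves: see :func:`benchmark_from_surfaces`.
    """
    if mode == "entropy-of-mean-rates":
        raise ValidationError(
            "mode 'entropy-of-mean-rates' needs rate surfaces; "
            "use benchmark_from_surfaces"
        )
    if mode != "mean-of-entropy":
        raise ValidationError(f"unknown benchmark mode {mode!r}")
    if len(results) < 2:
        raise ValidationError("benchmark needs at least two populations")
    years = {r.year for r in results}
    omegas = {r.n_cohorts for r in results}
    if len(years) != 1 or len(omegas) != 1:
        raise ValidationError(
            f"mismatched years {sorted(years)} or omegas across populations"
        )
    return BenchmarkCAL(
        year=results[0].year,
        cal=float(np.mean([r.cal for r in results])),
        cal_dagger=float(np.mean([r.cal_dagger for r in results])),
        h_cal=float(np.mean([r.h_cal for r in results])),
        n_cohorts=results[0].n_cohorts,
        n_populations=len(results),
    )


def benchmark_from_surfaces(
    surfaces: Sequence[MortalitySurface],
    year: int,
    omega: int | None = None,
    step: float = 1.0,
) -> BenchmarkCAL:
    """Sensitivity-mode benchmark: average the rate surfaces cell-wise, then
    compute the CAL measures of the averaged surface."""
    if len(surfaces) < 2:
        raise ValidationError("benchmark needs at least two populations")
    first = surfaces[0]
    for s in surfaces[1:]:
        if not (
            np.array_equal(s.ages, first.ages) and np.array_equal(s.years, first.years)
        ):
            raise ValidationError("surfaces must share age and year grids")
    mean_surface = MortalitySurface(
        ages=first.ages,
        years=first.years,
        rates=np.mean([s.rates for s in surfaces], axis=0),
        population_label="mean-rates benchmark",
    )
    r = cal_entropy(mean_surface, year, omega, step)
    return BenchmarkCAL(
        year=r.year,
        cal=r.cal,
        cal_dagger=r.cal_dagger,
        h_cal=r.h_cal,
        n_cohorts=r.n_cohorts,
        n_populations=len(surfaces),
        mode="entropy-of-mean-rates",
    )


def _check_positive(r, who: str) -> None:
    if r.cal <= 0 or r.cal_dagger <= 0 or r.h_cal <= 0:
        raise DomainError(
            f"{who}: CAL, CAL-dagger and H_CAL must be positive to take "
            f"log-ratios (got {r.cal}, {r.cal_dagger}, {r.h_cal})"
        )


def _h_tilde(pop, bench) -> float:
    """Logarithmic-mean entropy scale; arithmetic mean in the degenerate case."""
    d = np.log(pop.cal_dagger / bench.cal_dagger) - np.log(pop.cal / bench.cal)
    if abs(d) > _LOG_TOL:
        return (pop.h_cal - bench.h_cal) / d
    return 0.5 * (pop.h_cal + bench.h_cal)


def gap_decompose(pop: CALResult, bench, population: str = "") -> GapDecomposition:
    """Split H_pop - H_bench into lifespan-variation and longevity parts.

    The parts sum to the gap exactly.  ``bench`` is any object with year,
    cal, cal_dagger and h_cal attributes (another population or a benchmark).
    """
    if pop.year != bench.year:
        raise ValidationError(f"year mismatch: {pop.year} vs {bench.year}")
    if getattr(pop, "n_cohorts", None) != getattr(bench, "n_cohorts", None):
        raise ValidationError("population and benchmark use different omega")
    _check_positive(pop, "population")
    _check_positive(bench, "benchmark")
    gap = pop.h_cal - bench.h_cal
    r_dag = float(np.log(pop.cal_dagger / bench.cal_dagger))
    r_cal = float(np.log(pop.cal / bench.cal))
    d = r_dag - r_cal
    if abs(d) > _LOG_TOL:
        h_tilde = gap / d
        c_var = h_tilde * r_dag
        c_lon = -h_tilde * r_cal
    else:
        h_tilde = 0.5 * (pop.h_cal + bench.h_cal)
        c_var = h_tilde * r_dag
        c_lon = gap - c_var  # forces exact additivity in the degenerate branch
    return GapDecomposition(
        year=pop.year,
        population=population,
        gap=gap,
        contrib_variation=c_var,
        contrib_longevity=c_lon,
    )


def gap_change_decompose(
    pop_series: Sequence[CALResult],
    bench_series: Sequence,
    year: int,
    population: str = "",
) -> GapChangeDecomposition:
    """Split the change of the gap between year-1 and year into three terms."""
    pop = {r.year: r for r in pop_series}
    ben = {r.year: r for r in bench_series}
    for t in (year - 1, year):
        if t not in pop or t not in ben:
            raise ValidationError(
                f"both population and benchmark must cover years "
                f"{year - 1} and {year}; missing {t}"
            )
    prev_p, cur_p = pop[year - 1], pop[year]
    prev_b, cur_b = ben[year - 1], ben[year]
    for r, who in ((prev_p, "population"), (cur_p, "population"),
                   (prev_b, "benchmark"), (cur_b, "benchmark")):
        _check_positive(r, who)

    def brackets(p, b):
        r_dag = float(np.log(p.cal_dagger / b.cal_dagger))
        r_cal = float(np.log(p.cal / b.cal))
        return _h_tilde(p, b), r_dag, r_cal

    h0, rd0, rc0 = brackets(prev_p, prev_b)
    h1, rd1, rc1 = brackets(cur_p, cur_b)
    d0, d1 = rd0 - rc0, rd1 - rc1

    term_benchmark = (h1 - h0) * 0.5 * (d0 + d1)
    term_variation = 0.5 * (h0 + h1) * (rd1 - rd0)
    term_longevity = -0.5 * (h0 + h1) * (rc1 - rc0)
    total = (cur_p.h_cal - cur_b.h_cal) - (prev_p.h_cal - prev_b.h_cal)
    residual = total - (term_benchmark + term_variation + term_longevity)
    return GapChangeDecomposition(
        year_pair=(year - 1, year),
        population=population,
        total_change=total,
        term_benchmark=term_benchmark,
        term_variation=term_variation,
        term_longevity=term_longevity,
        residual=residual,
    )


def _components(d) -> dict[str, float]:
    if isinstance(d, GapDecomposition):
        return {"variation": d.contrib_variation, "longevity": d.contrib_longevity}
    if isinstance(d, GapChangeDecomposition):
        return {
            "benchmark": d.term_benchmark,
            "variation": d.term_variation,
            "longevity": d.term_longevity,
        }
    raise ValidationError(f"cannot take shares of {type(d).__name__}")


def component_shares(decomps: Sequence, window: int = 5) -> list[ShareSeries]:
    """Per-component share of the total absolute contribution, rolling-mean
    smoothed.

    share_i(t) = |c_i(t)| / sum_j |c_j(t)|, then a centered rolling mean of
    odd width ``window`` that shrinks at the series edges.  Years where every
    component is zero have undefined shares; they are left missing and
    excluded from the rolling mean.
    """
    if not decomps:
        raise ValidationError("empty decomposition sequence")
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be an odd integer >= 1, got {window}")
    years = [
        d.year if isinstance(d, GapDecomposition) else d.year_pair[1] for d in decomps
    ]
    rows = [_components(d) for d in decomps]
    names = list(rows[0])
    if any(list(r) != names for r in rows):
        raise ValidationError("mixed decomposition types in one share series")
    raw = pd.DataFrame(rows, index=years).abs()
    totals = raw.sum(axis=1)
    shares = raw.div(totals, axis=0)
    shares[totals == 0] = np.nan
    rolled = shares.rolling(window, center=True, min_periods=1).mean()
    return [
        ShareSeries(
            component=name,
            years=np.asarray(years),
            share=rolled[name].to_numpy(),
            window=window,
        )
        for name in names
    ]


def crossover_detect(years: Sequence[int], gaps: Sequence[float]) -> list[int]:
    """Years where the gap series changes sign.

    Zero gaps attach to the following sign (trailing zeros to the preceding
    one), so a -, 0, + run reports one crossover at the year the series
    leaves the old sign.
    """
    years = list(years)
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size < 2 or len(years) != gaps.size:
        raise ValidationError("need >= 2 (year, gap) pairs")
    signs = np.sign(gaps)
    for i in range(signs.size - 2, -1, -1):  # zeros take the next sign
        if signs[i] == 0:
            signs[i] = signs[i + 1]
    if signs[-1] == 0 and signs.size > 1:
        signs[-1] = signs[-2]
    out = []
    for i in range(1, signs.size):
        if signs[i - 1] != 0 and signs[i] != 0 and signs[i] != signs[i - 1]:
            out.append(years[i])
    return out


# -- tabular output ----------------------------------------------------------


def gap_frame(decomps: Sequence[GapDecomposition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "year": d.year,
                "population": d.population,
                "gap": d.gap,
                "contrib_variation": d.contrib_variation,
                "contrib_longevity": d.contrib_longevity,
            }
            for d in decomps
        ]
    )


def gap_change_frame(decomps: Sequence[GapChangeDecomposition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "year_from": d.year_pair[0],
                "year_to": d.year_pair[1],
                "population": d.population,
                "total_change": d.total_change,
                "term_benchmark": d.term_benchmark,
                "term_variation": d.term_variation,
                "term_longevity": d.term_longevity,
                "residual": d.residual,
            }
            for d in decomps
        ]
    )
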