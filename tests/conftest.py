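"""Shared synthetic fixtures: every test input is generated at run time."""

import numpy as np
import pytest

from calentropy import MortalitySurface, build_surface, cal_series, divergence_pair
from calentropy.synthetic import ScenarioSpec


@pytest.fixture(scope="session")
def stationary_spec():
    return ScenarioSpec(improvement_rho=0.0, year_start=1900, year_end=2015)


@pytest.fixture(scope="session")
def stationary_surface(stationary_spec):
    """Time-invariant Gompertz-Makeham surface: the central consistency oracle."""
    return build_surface(stationary_spec)


@pytest.fixture(scope="session")
def improving_surface():
    """Standard improving scenario, long enough for full CAL coverage."""
    return build_surface(ScenarioSpec(year_start=1800, year_end=2020))


@pytest.fixture(scope="session")
def shock_surface():
    """Standard scenario with a one-year x3 mortality shock in 2000."""
    return build_surface(ScenarioSpec(shocks=((2000, 3.0),)))


@pytest.fixture(scope="session")
def variation_pair():
    """Pair diverging only in lifespan variation (CAL pinned), with CAL series."""
    spec = ScenarioSpec(improvement_rho=0.0, year_start=1900, year_end=2040)
    a, b = divergence_pair(spec, variation_only=True, omega=110)
    years = range(2010, 2041)
    return (
        a,
        b,
        cal_series(a, years, omega=110),
        cal_series(b, years, omega=110),
    )


@pytest.fixture(scope="session")
def longevity_pair():
    """Pair diverging only in longevity (CAL-dagger pinned), with CAL series."""
    spec = ScenarioSpec(improvement_rho=0.0, year_start=1900, year_end=2040)
    a, b = divergence_pair(spec, variation_only=False, omega=110)
    years = range(2010, 2041)
    return (
        a,
        b,
        cal_series(a, years, omega=110),
        cal_series(b, years, omega=110),
    )


@pytest.fixture
def tiny_surface():
    """5 ages x 3 years with distinct, hand-readable rates."""
    ages = np.arange(5)
    years = np.arange(2000, 2003)
    rates = 0.01 + 0.001 * ages[:, None] + 0.0001 * (years - 2000)[None, :]
    return MortalitySurface(ages=ages, years=years, rates=rates, population_label="tiny")
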