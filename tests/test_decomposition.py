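"""Gap and gap-change decompositions: exactness, antisymmetry, attribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calentropy import (
    CALResult,
    DomainError,
    ValidationError,
    benchmark_average,
    benchmark_from_surfaces,
    build_surface,
    cal_entropy,
    component_shares,
    crossover_detect,
    gap_change_decompose,
    gap_change_frame,
    gap_decompose,
    gap_frame,
)
from calentropy.synthetic import ScenarioSpec


def result(cal, dagger, year=2000, n=111):
    return CALResult(year=year, cal=cal, cal_dagger=dagger,
                     h_cal=dagger / cal, n_cohorts=n)


positive = st.floats(min_value=1.0, max_value=120.0,
                     allow_nan=False, allow_infinity=False)


class TestGapDecompose:
    def test_worked_example_same_entropy_different_makeup(self):
        # CAL-dagger/CAL of 10/50 and 15/75 both give entropy 0.2: the gap is
        # zero but the decomposition shows offsetting variation and longevity
        pop, bench = result(50.0, 10.0), result(75.0, 15.0)
        d = gap_decompose(pop, bench)
        assert pop.h_cal == pytest.approx(0.2)
        assert bench.h_cal == pytest.approx(0.2)
        assert d.gap == pytest.approx(0.0, abs=1e-15)
        assert d.contrib_variation == pytest.approx(0.2 * np.log(10 / 15), abs=1e-12)
        assert d.contrib_variation == pytest.approx(-0.08109302, abs=1e-7)
        assert d.contrib_longevity == pytest.approx(+0.08109302, abs=1e-7)
        assert d.contrib_variation + d.contrib_longevity == pytest.approx(d.gap, abs=1e-15)

    def test_identical_populations_all_zero(self):
        d = gap_decompose(result(70.0, 11.0), result(70.0, 11.0))
        assert d.gap == d.contrib_variation == d.contrib_longevity == 0.0

    def test_equal_cal_puts_whole_gap_in_variation(self):
        d = gap_decompose(result(70.0, 12.0), result(70.0, 10.0))
        assert d.contrib_longevity == 0.0
        assert d.contrib_variation == pytest.approx(d.gap, abs=1e-15)

    @given(cal_p=positive, dag_p=positive, cal_b=positive, dag_b=positive)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_additivity_and_antisymmetry(self, cal_p, dag_p, cal_b, dag_b):
        pop, bench = result(cal_p, dag_p), result(cal_b, dag_b)
        d = gap_decompose(pop, bench)
        scale = max(abs(d.gap), 1.0)
        assert d.contrib_variation + d.contrib_longevity == pytest.approx(
            d.gap, abs=1e-10 * scale
        )
        r = gap_decompose(bench, pop)
        assert r.gap == pytest.approx(-d.gap, abs=1e-12 * scale)
        assert r.contrib_variation == pytest.approx(-d.contrib_variation, abs=1e-10 * scale)
        assert r.contrib_longevity == pytest.approx(-d.contrib_longevity, abs=1e-10 * scale)

    def test_additivity_holds_for_mean_benchmark(self):
        members = [result(70.0, 10.0), result(80.0, 12.0), result(75.0, 13.0)]
        bench = benchmark_average(members)
        for pop in members:
            d = gap_decompose(pop, bench)
            assert d.contrib_variation + d.contrib_longevity == pytest.approx(
                d.gap, abs=1e-12
            )

    def test_domain_errors(self):
        from types import SimpleNamespace

        bad = SimpleNamespace(year=2000, n_cohorts=111, cal=-1.0,
                              cal_dagger=10.0, h_cal=0.2)
        with pytest.raises(DomainError):
            gap_decompose(result(70.0, 10.0), bad)
        with pytest.raises(ValidationError):
            gap_decompose(result(70.0, 10.0), result(70.0, 10.0, year=2001))


class TestBenchmark:
    def test_mean_of_entropy(self):
        members = [result(50.0, 5.0), result(50.0, 10.0), result(50.0, 15.0)]
        b = benchmark_average(members)
        assert b.h_cal == pytest.approx(0.2)  # mean of 0.1, 0.2, 0.3
        assert b.cal == pytest.approx(50.0)

    def test_single_population_rejected(self):
        with pytest.raises(ValidationError):
            benchmark_average([result(50.0, 5.0)])

    def test_identical_members_reproduce_member(self):
        members = [result(70.0, 10.0)] * 3
        b = benchmark_average(members)
        assert (b.cal, b.cal_dagger, b.h_cal) == (70.0, 10.0, 1.0 / 7.0)

    def test_year_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            benchmark_average([result(70.0, 10.0), result(70.0, 10.0, year=1999)])

    def test_mean_rates_mode_on_identical_surfaces(self, stationary_surface):
        b = benchmark_from_surfaces([stationary_surface, stationary_surface], 2012, omega=110)
        r = cal_entropy(stationary_surface, 2012, omega=110)
        assert b.h_cal == pytest.approx(r.h_cal, abs=1e-12)
        assert b.mode == "entropy-of-mean-rates"

    def test_mean_rates_mode_needs_surfaces(self):
        with pytest.raises(ValidationError, match="benchmark_from_surfaces"):
            benchmark_average([result(70.0, 10.0), result(75.0, 11.0)],
                              mode="entropy-of-mean-rates")


class TestGapChange:
    def test_stationary_all_terms_zero(self):
        pop = [result(70.0, 10.0, year=y) for y in (1999, 2000)]
        ben = [result(72.0, 10.5, year=y) for y in (1999, 2000)]
        ch = gap_change_decompose(pop, ben, 2000)
        assert ch.total_change == 0.0
        assert ch.term_benchmark == ch.term_variation == ch.term_longevity == 0.0
        assert ch.residual == 0.0

    def test_terms_sum_exactly(self, variation_pair):
        _, _, series_a, series_b = variation_pair
        for year in range(2015, 2040, 4):
            ch = gap_change_decompose(series_b, series_a, year)
            s = ch.term_benchmark + ch.term_variation + ch.term_longevity
            assert s + ch.residual == pytest.approx(ch.total_change, abs=1e-15)
            assert abs(ch.residual) < 1e-14

    def test_variation_only_change_attributed_to_variation(self, variation_pair):
        _, _, series_a, series_b = variation_pair
        for year in range(2012, 2041):
            ch = gap_change_decompose(series_b, series_a, year)
            total_abs = (
                abs(ch.term_benchmark) + abs(ch.term_variation) + abs(ch.term_longevity)
            )
            assert abs(ch.term_variation) / total_abs >= 0.95

    def test_benchmark_term_sign(self):
        # pop static, benchmark entropy rising; bracket R+ - R is positive
        pop = [result(70.0, 10.0, year=y) for y in (1999, 2000)]
        ben = [result(80.0, 10.0, year=1999), result(80.0, 10.4, year=2000)]
        ch = gap_change_decompose(pop, ben, 2000)
        d_bar = np.mean([
            np.log(10.0 / 10.0) - np.log(70.0 / 80.0),
            np.log(10.0 / 10.4) - np.log(70.0 / 80.0),
        ])
        d_h_bench = 10.4 / 80.0 - 10.0 / 80.0
        assert d_bar > 0 and d_h_bench > 0
        assert np.sign(ch.term_benchmark) == np.sign(d_h_bench * d_bar)

    def test_residual_stays_negligible_as_changes_shrink(self):
        # the midpoint scheme obeys the discrete product rule exactly, so the
        # residual is roundoff at any improvement pace
        for scale in (1.0, 0.5, 0.25):
            a = build_surface(ScenarioSpec(improvement_rho=0.012 * scale,
                                           year_start=1895, year_end=2010))
            b = build_surface(ScenarioSpec(improvement_rho=0.010 * scale,
                                           makeham_a=3.2e-5,
                                           year_start=1895, year_end=2010))
            sa = [cal_entropy(a, y, omega=110) for y in (2007, 2008)]
            sb = [cal_entropy(b, y, omega=110) for y in (2007, 2008)]
            ch = gap_change_decompose(sa, sb, 2008)
            assert abs(ch.residual) <= 1e-12 * max(abs(ch.total_change), 1e-6)

    def test_missing_year_rejected(self):
        pop = [result(70.0, 10.0, year=1999)]
        ben = [result(72.0, 10.0, year=y) for y in (1999, 2000)]
        with pytest.raises(ValidationError):
            gap_change_decompose(pop, ben, 2000)


class TestShares:
    def _gaps(self, contribs):
        from calentropy.decomposition import GapDecomposition

        return [
            GapDecomposition(year=2000 + i, population="x",
                             gap=v + l, contrib_variation=v, contrib_longevity=l)
            for i, (v, l) in enumerate(contribs)
        ]

    def test_share_values(self):
        shares = component_shares(self._gaps([(-0.03, 0.01)]), window=1)
        by_name = {s.component: s.share[0] for s in shares}
        assert by_name["variation"] == pytest.approx(0.75)
        assert by_name["longevity"] == pytest.approx(0.25)

    def test_window_one_is_raw(self):
        decomps = self._gaps([(-0.03, 0.01), (-0.02, 0.02), (0.01, 0.01)])
        raw = component_shares(decomps, window=1)
        np.testing.assert_allclose(raw[0].share, [0.75, 0.5, 0.5])

    def test_constant_shares_unchanged_by_rolling(self):
        decomps = self._gaps([(-0.03, 0.01)] * 10)
        rolled = component_shares(decomps, window=5)
        np.testing.assert_allclose(rolled[0].share, 0.75)

    def test_shares_sum_to_one(self):
        decomps = self._gaps([(-0.03, 0.01), (0.02, -0.05), (0.01, 0.04)])
        shares = component_shares(decomps, window=1)
        total = np.sum([s.share for s in shares], axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_all_zero_year_excluded(self):
        decomps = self._gaps([(-0.03, 0.01), (0.0, 0.0), (-0.03, 0.01)])
        shares = component_shares(decomps, window=3)
        for s in shares:
            assert not np.isnan(s.share[0])  # rolling mean skips the hole
        variation = next(s for s in shares if s.component == "variation")
        np.testing.assert_allclose(variation.share, 0.75)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            component_shares(self._gaps([(-0.03, 0.01)]), window=4)


class TestCrossovers:
    @pytest.mark.parametrize(
        "gaps, expected_idx",
        [
            ([-0.01, -0.005, 0.002], [2]),
            ([-0.01, -0.02, -0.001], []),
            ([-0.01, 0.0, 0.01], [1]),  # zero attaches to the following sign
            ([0.01, -0.01, 0.02], [1, 2]),
        ],
    )
    def test_crossover_years(self, gaps, expected_idx):
        years = list(range(2000, 2000 + len(gaps)))
        assert crossover_detect(years, gaps) == [years[i] for i in expected_idx]


class TestFrames:
    def test_gap_frames_have_expected_columns(self, variation_pair):
        _, _, series_a, series_b = variation_pair
        gaps = [gap_decompose(b, a, "B") for a, b in zip(series_a, series_b)]
        gf = gap_frame(gaps)
        assert list(gf.columns) == [
            "year", "population", "gap", "contrib_variation", "contrib_longevity",
        ]
        ch = [gap_change_decompose(series_b, series_a, y, "B") for y in (2015, 2016)]
        cf = gap_change_frame(ch)
        assert "residual" in cf.columns and len(cf) == 2
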