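"""Census-year assignment and secular-trend weighting of denominators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casepop.denominator import (
    assign_census_year,
    external_denominator,
    monthly_exposure_fraction,
    parental_age_exposure,
    secular_weighting,
)
from casepop.tables_io import PopulationReference, ReferenceKind

GRID = (1881, 1886, 1891, 1896, 1901, 1906, 1911)


def scalar_ref(payload):
    return PopulationReference(
        factor="urbanicity",
        kind=ReferenceKind.scalar_proportion_by_year,
        year_grid=tuple(sorted(payload)),
        payload=payload,
    )


class TestAssignCensusYear:
    @pytest.mark.parametrize(
        "year, expected",
        [(1885, 1886), (1881, 1881), (1879, 1881), (1913, 1911), (1888, 1886)],
    )
    def test_nearest(self, year, expected):
        assert assign_census_year(year, GRID) == expected

    def test_tie_breaks_to_earlier(self):
        assert assign_census_year(1900, (1896, 1904)) == 1896


class TestSecularWeighting:
    def test_constant_series(self):
        ref = scalar_ref({y: 0.40 for y in GRID})
        d = secular_weighting(ref, [1880, 1895, 1910])
        assert d.exposed_proportion == pytest.approx(0.40)

    def test_half_half(self):
        ref = scalar_ref({1881: 0.30, 1891: 0.40})
        d = secular_weighting(ref, [1881, 1891])
        assert d.exposed_proportion == pytest.approx(0.35)
        assert d.weights_used == {1881: 0.5, 1891: 0.5}

    def test_degenerate_weights(self):
        ref = scalar_ref({1881: 0.2, 1891: 0.5})
        d = secular_weighting(ref, [1891, 1891, 1890])
        assert d.exposed_proportion == pytest.approx(0.50)

    def test_empty_case_list(self):
        ref = scalar_ref({1881: 0.2})
        with pytest.raises(ValueError, match="empty"):
            secular_weighting(ref, [])

    def test_linear_interpolation_switch(self):
        ref = scalar_ref({1881: 0.30, 1891: 0.40})
        d = secular_weighting(ref, [1886], interpolation="linear")
        assert d.exposed_proportion == pytest.approx(0.35)


class TestMonthlyFraction:
    def test_uniform_months(self):
        ref = PopulationReference(
            factor="seasonality",
            kind=ReferenceKind.monthly_shares_by_year,
            year_grid=(1896,),
            payload={1896: tuple([1 / 12] * 12)},
        )
        d = monthly_exposure_fraction(ref, {12, 1, 2, 3})
        assert d.exposed_proportion == pytest.approx(1 / 3)

    def test_empty_window_rejected(self):
        ref = PopulationReference(
            factor="seasonality",
            kind=ReferenceKind.monthly_shares_by_year,
            year_grid=(1896,),
            payload={1896: tuple([1 / 12] * 12)},
        )
        with pytest.raises(ValueError, match="empty"):
            monthly_exposure_fraction(ref, set())

    def test_secular_weighting_of_monthly_tables(self):
        jan_heavy = (0.45,) + (0.05,) * 11
        feb_heavy = (0.05, 0.45) + (0.05,) * 10
        ref = PopulationReference(
            factor="seasonality",
            kind=ReferenceKind.monthly_shares_by_year,
            year_grid=(1881, 1891),
            payload={1881: jan_heavy, 1891: feb_heavy},
        )
        d = monthly_exposure_fraction(ref, {1}, [1881, 1881, 1891, 1891])
        assert d.exposed_proportion == pytest.approx(0.25)


def crosstab_ref(entry, years=(1901,)):
    return PopulationReference(
        factor="paternal_age",
        kind=ReferenceKind.parental_age_crosstab_by_year,
        year_grid=tuple(years),
        payload={y: entry for y in years},
    )


class TestParentalAge:
    def test_independence_gives_equal_stratum_odds(self):
        f_margin = {(25, 30): 0.3, (30, 35): 0.3, (35, 40): 0.25, (40, 45): 0.15}
        m_margin = {(25, 30): 0.6, (35, 40): 0.4}
        entry = {
            (fb, mb): fw * mw for fb, fw in f_margin.items() for mb, mw in m_margin.items()
        }
        d = parental_age_exposure(crosstab_ref(entry), 35)
        marginal = 0.25 + 0.15
        assert d.exposed_proportion == pytest.approx(marginal)
        assert d.strata["mother_lt"] == pytest.approx(marginal)
        assert d.strata["mother_ge"] == pytest.approx(marginal)

    def test_misaligned_threshold_rejected(self):
        entry = {((30, 35), (30, 35)): 0.5, ((35, 40), (30, 35)): 0.5}
        with pytest.raises(ValueError, match="band"):
            parental_age_exposure(crosstab_ref(entry), 33)


class TestExternal:
    def test_migrant_share(self):
        d = external_denominator(0.081, "men aged 35+, France 1954")
        assert d.exposed_proportion == 0.081
        assert d.provenance == "external_estimate"

    def test_midrange(self):
        assert external_denominator(0.5, "").exposed_proportion == 0.5

    @pytest.mark.parametrize("p", [1.2, 0.0, 1.0, -0.1])
    def test_out_of_range(self, p):
        with pytest.raises(ValueError):
            external_denominator(p, "")


year_series = st.dictionaries(
    st.integers(1870, 1920), st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=8
)
case_years = st.lists(st.integers(1860, 1930), min_size=1, max_size=50)


@given(year_series, case_years)
def test_convexity(payload, years):
    d = secular_weighting(scalar_ref(payload), years)
    values = list(payload.values())
    assert min(values) - 1e-12 <= d.exposed_proportion <= max(values) + 1e-12


@given(year_series, case_years, st.randoms(use_true_random=False))
def test_permutation_invariance(payload, years, rnd):
    ref = scalar_ref(payload)
    shuffled = list(years)
    rnd.shuffle(shuffled)
    assert secular_weighting(ref, shuffled) == secular_weighting(ref, years)


@given(year_series, case_years)
def test_refinement_consistency(payload, years):
    """Splitting a grid year's weight across entries with the same proportion
    leaves the weighted proportion unchanged."""
    d = secular_weighting(scalar_ref(payload), years)
    total = 0.0
    for year, w in d.weights_used.items():
        total += (w / 2) * payload[year] + (w / 2) * payload[year]
    assert total == pytest.approx(d.exposed_proportion)
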