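"""Odds ratios, fixed-denominator Woolf intervals, stratified adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casepop.denominator import WeightedDenominator, external_denominator
from casepop.or_stats import (
    Stratum,
    bootstrap_ci,
    compute_association,
    odds_ratio,
    stratified_adjusted_or,
    wald_p_value,
    woolf_ci_fixed_denominator,
)


class TestOddsRatio:
    def test_first_born_vs_population(self):
        assert odds_ratio(0.4815, 0.3037) == pytest.approx(2.13, abs=0.005)

    def test_migration(self):
        assert odds_ratio(0.0768, 0.081) == pytest.approx(0.94, abs=0.005)

    def test_null(self):
        assert odds_ratio(0.5, 0.5) == 1.0

    def test_counts_form(self):
        assert odds_ratio((30, 70), 0.3) == pytest.approx((30 / 70) / (0.3 / 0.7))

    @pytest.mark.parametrize("p_case", [0.0, 1.0])
    def test_degenerate_proportion_refused(self, p_case):
        with pytest.raises(ValueError, match="continuity"):
            odds_ratio(p_case, 0.5)


class TestWoolfCI:
    def test_first_born_interval(self):
        # 48.15% of 1972 cases -> a=950, b=1022, population side fixed
        or_val = odds_ratio(950 / 1972, 0.3037)
        lo, hi = woolf_ci_fixed_denominator(950, 1022, or_val)
        assert (round(lo, 2), round(hi, 2)) == (1.95, 2.33)

    def test_symmetry_on_log_scale(self):
        lo, hi = woolf_ci_fixed_denominator(200, 200, 1.0)
        se = math.sqrt(2 / 200)
        assert lo == pytest.approx(math.exp(-1.959964 * se), rel=1e-6)
        assert hi == pytest.approx(math.exp(1.959964 * se), rel=1e-6)

    def test_urban_interval(self):
        lo, hi = woolf_ci_fixed_denominator(1303, 243, 7.86)
        assert lo == pytest.approx(6.85, abs=0.01)
        assert hi == pytest.approx(9.01, abs=0.01)

    def test_zero_cell_refused_by_default(self):
        with pytest.raises(ValueError, match="continuity"):
            woolf_ci_fixed_denominator(0, 100, 1.0)

    def test_continuity_flag(self):
        lo, hi = woolf_ci_fixed_denominator(0, 100, 1.0, continuity=True)
        assert 0 < lo < 1 < hi


class TestStratifiedAdjustment:
    def test_single_stratum_reduces_to_crude(self):
        or_val = odds_ratio((30, 70), 0.2)
        lo, hi = woolf_ci_fixed_denominator(30, 70, or_val)
        or_adj, lo_adj, hi_adj = stratified_adjusted_or([Stratum(30, 70, 0.2)])
        assert (or_adj, lo_adj, hi_adj) == pytest.approx((or_val, lo, hi))

    def test_homogeneous_strata_pool_to_common_or(self):
        # both strata have OR exactly 2 against their own population odds
        s1 = Stratum(40, 60, (40 / 60) / 2 / (1 + (40 / 60) / 2))
        s2 = Stratum(30, 90, (30 / 90) / 2 / (1 + (30 / 90) / 2))
        or_adj, _, _ = stratified_adjusted_or([s1, s2])
        assert or_adj == pytest.approx(2.0)

    def test_inverse_variance_pooling_hand_computation(self):
        # stratum ORs 1.714 and 1.25 with Woolf weights 21 and 16
        strata = [Stratum(30, 70, 0.2), Stratum(20, 80, 1 / 6)]
        or_adj, lo, hi = stratified_adjusted_or(strata)
        w1, w2 = 21.0, 16.0
        expected = math.exp((w1 * math.log((30 / 70) / 0.25) + w2 * math.log((20 / 80) / 0.2)) / (w1 + w2))
        assert or_adj == pytest.approx(expected)
        assert or_adj == pytest.approx(1.4954, abs=1e-4)
        se = 1 / math.sqrt(w1 + w2)
        assert lo == pytest.approx(or_adj * math.exp(-1.959964 * se), rel=1e-6)

    def test_empty_stratum_named(self):
        with pytest.raises(ValueError, match="empty cell"):
            stratified_adjusted_or([Stratum(10, 20, 0.3), Stratum(0, 5, 0.3, name="older")])

    def test_mantel_haenszel_close_to_woolf_for_balanced_strata(self):
        strata = [Stratum(30, 70, 0.2), Stratum(20, 80, 1 / 6)]
        or_w, _, _ = stratified_adjusted_or(strata, scheme="woolf")
        or_mh, _, _ = stratified_adjusted_or(strata, scheme="mantel-haenszel")
        assert or_mh == pytest.approx(or_w, rel=0.05)


counts = st.integers(1, 10_000)
props = st.floats(0.01, 0.99)


@given(counts, counts, props)
def test_inversion_symmetry(a, b, p_pop):
    """Swapping exposed/unexposed on both sides inverts the OR and CI."""
    or_val = odds_ratio((a, b), p_pop)
    or_inv = odds_ratio((b, a), 1 - p_pop)
    assert or_inv == pytest.approx(1 / or_val, rel=1e-9)
    lo, hi = woolf_ci_fixed_denominator(a, b, or_val)
    lo_inv, hi_inv = woolf_ci_fixed_denominator(b, a, or_inv)
    assert lo_inv == pytest.approx(1 / hi, rel=1e-9)
    assert hi_inv == pytest.approx(1 / lo, rel=1e-9)


@given(counts, counts, props)
def test_ci_brackets_or(a, b, p_pop):
    or_val = odds_ratio((a, b), p_pop)
    lo, hi = woolf_ci_fixed_denominator(a, b, or_val)
    assert lo < or_val < hi


def test_bootstrap_close_to_woolf_smoke():
    or_val = odds_ratio((200, 300), 0.35)
    lo, hi = woolf_ci_fixed_denominator(200, 300, or_val)
    blo, bhi = bootstrap_ci(200, 300, 0.35, n_resamples=2000, seed=5)
    assert blo == pytest.approx(lo, rel=0.07)
    assert bhi == pytest.approx(hi, rel=0.07)


class TestComputeAssociation:
    def test_null_association(self):
        d = external_denominator(0.5, "")
        res = compute_association("x", 100, 100, d)
        assert res.odds_ratio == 1.0
        assert res.ci_low < 1.0 < res.ci_high
        assert res.p_value == pytest.approx(1.0)

    def test_report_rounding(self):
        d = external_denominator(0.3037, "")
        res = compute_association("first_born", 950, 1022, d)
        assert (res.odds_ratio, res.ci_low, res.ci_high) == (2.13, 1.95, 2.33)
        assert res.pct_exposed_cases == pytest.approx(48.17, abs=0.01)

    def test_stratified_path_sets_adjustment(self):
        d = WeightedDenominator(
            factor="paternal_age", exposed_proportion=0.3, weights_used={}, provenance="unweighted"
        )
        res = compute_association(
            "paternal_age", 50, 150, d,
            strata=[Stratum(30, 70, 0.3), Stratum(20, 80, 0.3)],
            adjusted_for=("maternal_age",),
        )
        assert res.adjusted_for == ("maternal_age",)
        assert res.ci_low <= res.odds_ratio <= res.ci_high
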