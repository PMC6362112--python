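"""Odds ratios and fixed-denominator Woolf confidence intervals.

The design compares a finite case sample against a general population
summarised by official statistics, so the population exposed proportion is
treated as a **fixed** quantity contributing no sampling variance. The log
odds ratio then carries only the case-side Woolf variance:

    OR = [p_case / (1 - p_case)] / [p_pop / (1 - p_pop)]
    SE(log OR) = sqrt(1/a + 1/b),  a = exposed cases, b = unexposed cases
    95% CI = exp(log OR +/- z * SE),  z = Phi^{-1}(0.975) = 1.959964...

Covariate adjustment (maternal age, for the paternal-age factor) stratifies
the cases on the covariate, takes each stratum's log OR against that
stratum's fixed population odds, and pools by inverse-variance (Woolf)
weights w_i = 1/(1/a_i + 1/b_i); Mantel-Haenszel pooling is available as an
alternative scheme. Zero cells are refused rather than continuity-corrected
by default; a Haldane-Anscombe +0.5 correction sits behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .denominator import WeightedDenominator
from .tables_io import AssociationResult

__all__ = [
    "Stratum",
    "CasePopulationTable",
    "odds_ratio",
    "woolf_ci_fixed_denominator",
    "stratified_adjusted_or",
    "bootstrap_ci",
    "wald_p_value",
    "compute_association",
]


@dataclass(frozen=True)
class Stratum:
    """Case counts and the fixed population exposed proportion in one stratum."""

    a: int  # exposed cases
    b: int  # unexposed cases
    p_pop: float  # population exposed proportion (fraction)
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.p_pop < 1.0:
            raise ValueError(f"stratum {self.name!r}: p_pop must be in (0,1), got {self.p_pop}")


@dataclass(frozen=True)
class CasePopulationTable:
    """Marginal case counts against a fixed population proportion, with
    optional covariate strata that must sum to the margins."""

    a: int
    b: int
    p_pop: float
    strata: Optional[tuple[Stratum, ...]] = None

    def __post_init__(self) -> None:
        if self.a + self.b < 1:
            raise ValueError("need at least one case")
        if not 0.0 < self.p_pop < 1.0:
            raise ValueError(f"p_pop must be in (0,1), got {self.p_pop}")
        if self.strata is not None:
            if sum(s.a for s in self.strata) != self.a or sum(s.b for s in self.strata) != self.b:
                raise ValueError("stratum counts do not sum to the marginal counts")


def _z(level: float) -> float:
    return float(stats.norm.ppf(0.5 + level / 2.0))


def odds_ratio(
    p_case: Union[float, tuple[int, int]], p_pop: float
) -> float:
    """Case exposure odds over fixed population exposure odds.

    ``p_case`` is either an exposed fraction or an ``(a, b)`` count pair.
    Degenerate proportions (0 or 1 on either side) are refused; use the
    continuity-correction flag of the CI routines for sparse tables.
    """
    if isinstance(p_case, tuple):
        a, b = p_case
        if a <= 0 or b <= 0:
            raise ValueError(
                f"degenerate case counts a={a}, b={b}; "
                "enable the +0.5 continuity correction to proceed"
            )
        case_odds = a / b
    else:
        if not 0.0 < p_case < 1.0:
            raise ValueError(
                f"degenerate case proportion {p_case}; "
                "supply counts with the continuity correction for sparse tables"
            )
        case_odds = p_case / (1.0 - p_case)
    if not 0.0 < p_pop < 1.0:
        raise ValueError(f"degenerate population proportion {p_pop}")
    return case_odds / (p_pop / (1.0 - p_pop))


def woolf_ci_fixed_denominator(
    a: int,
    b: int,
    or_value: float,
    level: float = 0.95,
    continuity: bool = False,
) -> tuple[float, float]:
    """Woolf CI with the population side fixed: SE(log OR) = sqrt(1/a + 1/b)."""
    if a < 1 or b < 1:
        if not continuity:
            raise ValueError(
                f"zero/negative cell (a={a}, b={b}); pass continuity=True for "
                "a Haldane-Anscombe +0.5 correction"
            )
        a, b = a + 0.5, b + 0.5  # type: ignore[assignment]
    se = math.sqrt(1.0 / a + 1.0 / b)
    z = _z(level)
    log_or = math.log(or_value)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def stratified_adjusted_or(
    strata: Sequence[Stratum],
    level: float = 0.95,
    scheme: str = "woolf",
) -> tuple[float, float, float]:
    """Covariate-adjusted OR pooled across strata, with its CI.

    ``woolf``: inverse-variance pooling of the per-stratum log ORs, each
    taken against the stratum's fixed population odds; pooled
    SE = 1/sqrt(sum w_i). ``mantel-haenszel``: MH-style pooling with the
    population odds acting as the (fixed) control arm, CI from the Woolf
    pooled SE.
    """
    if not strata:
        raise ValueError("no strata supplied")
    for s in strata:
        if s.a < 1 or s.b < 1:
            raise ValueError(f"stratum {s.name or strata.index(s)} has an empty cell (a={s.a}, b={s.b})")
    log_ors = [math.log((s.a / s.b) / (s.p_pop / (1 - s.p_pop))) for s in strata]
    weights = [1.0 / (1.0 / s.a + 1.0 / s.b) for s in strata]
    if scheme == "woolf":
        pooled_log = sum(w * lo for w, lo in zip(weights, log_ors)) / sum(weights)
    elif scheme == "mantel-haenszel":
        n = sum(s.a + s.b for s in strata)
        num = sum(s.a * (1 - s.p_pop) * (s.a + s.b) / n for s in strata)
        den = sum(s.b * s.p_pop * (s.a + s.b) / n for s in strata)
        pooled_log = math.log(num / den)
    else:
        raise ValueError(f"unknown pooling scheme {scheme!r}")
    se = 1.0 / math.sqrt(sum(weights))
    z = _z(level)
    return (
        math.exp(pooled_log),
        math.exp(pooled_log - z * se),
        math.exp(pooled_log + z * se),
    )


def bootstrap_ci(
    a: int,
    b: int,
    p_pop: float,
    n_resamples: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap of the case sample against the fixed denominator.

    Resampling the n = a + b exposure indicators with replacement is a
    Binomial(n, a/n) draw per replicate; the population proportion stays
    fixed, mirroring the Woolf convention. Serves as an independent check on
    the analytic interval.
    """
    n = a + b
    rng = np.random.default_rng(seed)
    a_star = rng.binomial(n, a / n, size=n_resamples)
    a_star = np.clip(a_star, 1, n - 1)  # immaterial for the a,b >= 100 regime
    ors = (a_star / (n - a_star)) / (p_pop / (1 - p_pop))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(ors, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def wald_p_value(or_value: float, se_log: float) -> float:
    """Two-sided p for H0: OR = 1 from the Wald z statistic."""
    z = abs(math.log(or_value)) / se_log
    return float(2.0 * stats.norm.sf(z))


def compute_association(
    factor: str,
    a: int,
    b: int,
    denominator: WeightedDenominator,
    strata: Optional[Sequence[Stratum]] = None,
    level: float = 0.95,
    continuity: bool = False,
    adjustment_scheme: str = "woolf",
    adjusted_for: Sequence[str] = (),
) -> AssociationResult:
    """Assemble one report row; stratified path when strata are supplied.

    Percentages, OR and CI are rounded to 2 decimals in the output; all
    internal computation is full precision.
    """
    n = a + b
    p_pop = denominator.exposed_proportion
    if strata:
        or_val, lo, hi = stratified_adjusted_or(strata, level=level, scheme=adjustment_scheme)
        se = 1.0 / math.sqrt(sum(1.0 / (1.0 / s.a + 1.0 / s.b) for s in strata))
        adjusted = tuple(adjusted_for) or ("covariate",)
    else:
        or_val = odds_ratio((a, b) if a > 0 and b > 0 else a / n, p_pop)
        lo, hi = woolf_ci_fixed_denominator(a, b, or_val, level=level, continuity=continuity)
        se = math.sqrt(1.0 / max(a, 0.5) + 1.0 / max(b, 0.5))
        adjusted = ()
    return AssociationResult(
        factor=factor,
        n_exposed_cases=a,
        n_cases=n,
        pct_exposed_cases=round(100.0 * a / n, 2),
        pct_exposed_population=round(100.0 * p_pop, 2),
        odds_ratio=round(or_val, 2),
        ci_low=round(lo, 2),
        ci_high=round(hi, 2),
        p_value=wald_p_value(or_val, se),
        adjusted_for=adjusted,
    )
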