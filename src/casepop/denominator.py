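"""Census-weighted population denominators.

Historical population data arrive as sparse per-census-year tables (census
years 1881, 1891, 1901, 1911 plus inter-census midpoints 1886, 1896, 1906;
parental ages only from 1892). Whenever the series shows a secular trend —
urban births rising, parental ages drifting — the per-year values are
weighted to match the case sample's birth-year distribution before a single
exposed-population proportion is formed.

Year matching assigns each case birth year to the nearest grid year (exact
ties break to the earlier year); linear interpolation between grid years is
available behind the ``interpolation`` switch for sensitivity analysis.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from .tables_io import PopulationReference, ReferenceKind

__all__ = [
    "WeightedDenominator",
    "assign_census_year",
    "secular_weighting",
    "monthly_exposure_fraction",
    "parental_age_exposure",
    "external_denominator",
]


@dataclass(frozen=True)
class WeightedDenominator:
    """A single exposed-population proportion with its provenance.

    ``weights_used`` records the case-derived weight on each grid year (empty
    for external estimates); ``strata`` optionally carries per-covariate-
    stratum exposed proportions (used by the maternal-age adjusted analysis).
    """

    factor: str
    exposed_proportion: float
    weights_used: dict[int, float] = field(default_factory=dict)
    provenance: Literal["weighted", "unweighted", "external_estimate"] = "weighted"
    strata: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.exposed_proportion <= 1.0:
            raise ValueError(f"exposed_proportion outside [0,1]: {self.exposed_proportion}")
        if self.weights_used:
            total = sum(self.weights_used.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"weights sum to {total}, expected 1")

    @property
    def odds(self) -> float:
        p = self.exposed_proportion
        return p / (1.0 - p)


def assign_census_year(birth_year: int, year_grid: Sequence[int]) -> int:
    """Nearest grid year; exact ties break to the earlier year."""
    if not year_grid:
        raise ValueError("empty year grid")
    return min(year_grid, key=lambda y: (abs(birth_year - y), y))


def _year_weights(
    case_birth_years: Iterable[int],
    year_grid: Sequence[int],
    interpolation: str,
) -> dict[int, float]:
    years = list(case_birth_years)
    if not years:
        raise ValueError("empty case list: no birth years to weight by")
    weights: Counter = Counter()
    if interpolation == "nearest":
        for y in years:
            weights[assign_census_year(y, year_grid)] += 1.0
    elif interpolation == "linear":
        grid = sorted(year_grid)
        for y in years:
            if y <= grid[0]:
                weights[grid[0]] += 1.0
            elif y >= grid[-1]:
                weights[grid[-1]] += 1.0
            else:
                hi = next(g for g in grid if g >= y)
                lo = max(g for g in grid if g <= y)
                if hi == lo:
                    weights[lo] += 1.0
                else:
                    frac = (y - lo) / (hi - lo)
                    weights[lo] += 1.0 - frac
                    weights[hi] += frac
    else:
        raise ValueError(f"unknown interpolation scheme {interpolation!r}")
    n = float(len(years))
    return {y: w / n for y, w in sorted(weights.items())}


def secular_weighting(
    reference: PopulationReference,
    case_birth_years: Iterable[int],
    interpolation: str = "nearest",
) -> WeightedDenominator:
    """Weight a per-year proportion series by the case birth-year distribution.

    weight(grid year) = fraction of cases assigned to it;
    exposed proportion = sum over grid years of weight x proportion.
    Convexity follows: the result lies within [min, max] of the inputs.
    """
    if reference.kind is not ReferenceKind.scalar_proportion_by_year:
        raise ValueError(f"expected scalar_proportion_by_year, got {reference.kind}")
    weights = _year_weights(case_birth_years, reference.year_grid, interpolation)
    prop = sum(w * float(reference.payload[y]) for y, w in weights.items())
    return WeightedDenominator(
        factor=reference.factor,
        exposed_proportion=prop,
        weights_used=weights,
        provenance="weighted" if len(reference.year_grid) > 1 else "unweighted",
    )


def monthly_exposure_fraction(
    reference: PopulationReference,
    month_window: Iterable[int],
    case_birth_years: Optional[Iterable[int]] = None,
    interpolation: str = "nearest",
) -> WeightedDenominator:
    """Fraction of births inside the month window, secularly weighted.

    Per grid year the window fraction is the sum of that year's monthly
    shares over the window; the per-year fractions are then combined with
    case-derived year weights. A single pooled row (1-year grid) needs no
    case years. Monthly shares are used as tabulated, with no adjustment for
    unequal month lengths.
    """
    if reference.kind is not ReferenceKind.monthly_shares_by_year:
        raise ValueError(f"expected monthly_shares_by_year, got {reference.kind}")
    window = sorted(set(month_window))
    if not window:
        raise ValueError("empty month window")
    if not set(window) <= set(range(1, 13)):
        raise ValueError(f"month window outside 1..12: {window}")
    per_year = {
        y: float(sum(reference.payload[y][m - 1] for m in window)) for y in reference.year_grid
    }
    if len(reference.year_grid) == 1:
        (year,) = reference.year_grid
        return WeightedDenominator(
            factor=reference.factor,
            exposed_proportion=per_year[year],
            weights_used={year: 1.0},
            provenance="unweighted",
        )
    if case_birth_years is None:
        raise ValueError("multi-year monthly reference requires case birth years")
    weights = _year_weights(case_birth_years, reference.year_grid, interpolation)
    prop = sum(w * per_year[y] for y, w in weights.items())
    return WeightedDenominator(
        factor=reference.factor,
        exposed_proportion=prop,
        weights_used=weights,
        provenance="weighted",
    )


def parental_age_exposure(
    reference: PopulationReference,
    paternal_threshold: int,
    case_birth_years: Optional[Iterable[int]] = None,
    interpolation: str = "nearest",
) -> WeightedDenominator:
    """Population paternal-age exposure from a father x mother band crosstab.

    Returns the marginal fraction of births with father's age at or above
    ``paternal_threshold`` (which must fall on a band boundary; the bands are
    5-year), plus — in ``strata`` — the within-stratum paternal exposed
    proportion for each maternal stratum (``mother_lt``/``mother_ge`` the same
    threshold), as the maternal-age adjusted analysis needs.
    """
    if reference.kind is not ReferenceKind.parental_age_crosstab_by_year:
        raise ValueError(f"expected parental_age_crosstab_by_year, got {reference.kind}")
    for year in reference.year_grid:
        for (fb, mb) in reference.payload[year]:
            for lo, hi in (fb, mb):
                if lo < paternal_threshold < hi:
                    raise ValueError(
                        f"threshold {paternal_threshold} cuts band {lo}-{hi - 1} "
                        f"in year {year}; it must align with a 5-year band boundary"
                    )
    if len(reference.year_grid) == 1 or case_birth_years is None:
        if len(reference.year_grid) > 1:
            raise ValueError("multi-year crosstab reference requires case birth years")
        weights = {reference.year_grid[0]: 1.0}
        provenance = "unweighted"
    else:
        weights = _year_weights(case_birth_years, reference.year_grid, interpolation)
        provenance = "weighted"

    pooled: dict = {}
    for year, w in weights.items():
        for key, share in reference.payload[year].items():
            pooled[key] = pooled.get(key, 0.0) + w * share

    marginal = sum(share for (fb, _), share in pooled.items() if fb[0] >= paternal_threshold)
    strata: dict[str, float] = {}
    for name, keep in (
        ("mother_lt", lambda mb: mb[1] <= paternal_threshold),
        ("mother_ge", lambda mb: mb[0] >= paternal_threshold),
    ):
        tot = sum(share for (_, mb), share in pooled.items() if keep(mb))
        exp = sum(
            share
            for (fb, mb), share in pooled.items()
            if keep(mb) and fb[0] >= paternal_threshold
        )
        strata[name] = exp / tot if tot > 0 else float("nan")
    return WeightedDenominator(
        factor=reference.factor,
        exposed_proportion=marginal,
        weights_used=weights,
        provenance=provenance,
        strata=strata,
    )


def external_denominator(proportion: float, label: str, factor: str = "migration") -> WeightedDenominator:
    """Wrap an externally estimated population proportion (e.g. the migrant
    share of men aged 35+, combined from census and public statistics) with
    ``external_estimate`` provenance."""
    if not 0.0 < proportion < 1.0:
        raise ValueError(f"external proportion must be in (0,1), got {proportion}")
    return WeightedDenominator(
        factor=f"{factor} [{label}]" if label else factor,
        exposed_proportion=proportion,
        weights_used={},
        provenance="external_estimate",
    )
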