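"""Seeded generator of a pseudo-population and an achiever-style case sample.

The generator emulates the statistical structure the analysis assumes — not
any historical cohort — so every stage of the pipeline can be exercised and
checked against known truth:

* individuals are drawn independently with birth year uniform on the
  configured range (default 1879-1913), birth month multinomial, an urban
  birth probability following a linear secular trend, maternal age from a
  discretised truncated normal with paternal age = maternal + a positive
  offset, a sibship size from a configurable distribution (default truncated
  geometric, mean about 3) and birth rank uniform within the sibship;
* the matching :class:`~casepop.tables_io.PopulationReference` tables are
  computed **exactly from the generator's parameters** (never from the
  sample) on the census-year grid, so estimator bias and sampling noise are
  separable;
* cases are selected among males by a logistic model on the binary
  exposures; each coefficient is the log of a target odds ratio, and in the
  rare-outcome regime the selection OR is (approximately) the
  case-population OR the pipeline estimates. The intercept is calibrated by
  bisection so the expected number of cases hits ``n_cases_target``.

All randomness flows from a single :func:`numpy.random.default_rng` (PCG64)
instance in a fixed draw order (year, month, sex, urban, maternal age,
paternal offset, born abroad, sibship size, rank; then selection), so a seed
pins the output byte-for-byte.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .birth_rank_null import POOL_RANK
from .tables_io import CaseRecord, PopulationReference, ReferenceKind

__all__ = ["SyntheticConfig", "generate_population", "select_cases", "to_case_records"]

#: Census-year grid for births 1879-1913; parental ages available from 1892.
CENSUS_GRID = (1881, 1886, 1891, 1896, 1901, 1906, 1911)
PARENTAL_GRID = (1892, 1896, 1901, 1906, 1911)

# Monthly birth shares of the historical general population, December-March
# share 34.17% (percent dialect, normalised at load).
DEFAULT_MONTHLY_SHARES = (8.67, 8.33, 9.17, 8.75, 8.58, 8.08, 8.33, 8.25, 8.0, 7.92, 7.75, 8.0)


def _truncated_geometric(mean: float = 3.0, max_size: int = 12) -> tuple[float, ...]:
    """Sibship-size distribution: geometric with the given untruncated mean,
    truncated and renormalised on 1..max_size."""
    q = 1.0 - 1.0 / mean
    p = np.array([(1 - q) * q ** (s - 1) for s in range(1, max_size + 1)])
    return tuple(p / p.sum())


class ParentalAgeModel(BaseModel):
    model_config = ConfigDict(frozen=True)

    mother_mean: float = 28.0
    mother_sd: float = Field(default=6.0, gt=0)
    offset_mean: float = 5.0
    offset_sd: float = Field(default=4.0, gt=0)
    age_min: int = 15
    age_max: int = 60


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_population: int = Field(default=200_000, gt=0)
    birth_year_range: tuple[int, int] = (1879, 1913)
    monthly_shares: tuple[float, ...] = DEFAULT_MONTHLY_SHARES
    urban_trend: tuple[float, float] = (0.35, 0.55)
    p_male: float = Field(default=0.51, gt=0, le=1)
    p_born_abroad: float = Field(default=0.081, gt=0, lt=1)
    parental_age_model: ParentalAgeModel = ParentalAgeModel()
    sibship_size_distribution: tuple[float, ...] = _truncated_geometric()
    selection_log_odds: dict[str, float] = Field(
        default_factory=lambda: {
            "seasonality": 0.0,
            "urbanicity": 0.0,
            "paternal_age": 0.0,
            "migration": 0.0,
            "first_born": 0.0,
        }
    )
    n_cases_target: int = Field(default=2000, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        shares = np.asarray(self.monthly_shares, dtype=float)
        if shares.shape != (12,):
            raise ValueError("monthly_shares must have 12 entries")
        if np.any(shares < 0):
            raise ValueError("monthly_shares must be non-negative")
        sib = np.asarray(self.sibship_size_distribution, dtype=float)
        if np.any(sib < 0) or not math.isclose(float(sib.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("sibship_size_distribution must be a probability vector")
        lo, hi = self.birth_year_range
        if hi < lo:
            raise ValueError("birth_year_range inverted")
        for p in self.urban_trend:
            if not 0.0 <= p <= 1.0:
                raise ValueError("urban_trend proportions must be in [0,1]")
        known = {"seasonality", "urbanicity", "paternal_age", "migration", "first_born", "maternal_age"}
        unknown = set(self.selection_log_odds) - known
        if unknown:
            raise ValueError(f"unknown selection factors: {sorted(unknown)}")
        # rare-outcome regime: cases must stay a small minority of males
        if self.n_cases_target > 0.25 * self.n_population * self.p_male:
            raise ValueError(
                "n_cases_target too large for the rare-outcome regime "
                f"({self.n_cases_target} vs {self.n_population} population)"
            )
        return self

    @property
    def monthly_probs(self) -> np.ndarray:
        shares = np.asarray(self.monthly_shares, dtype=float)
        return shares / shares.sum()


# ---------------------------------------------------------------------------
# Exact discrete parental-age model shared by the sampler and the reference

def _mother_distribution(m: ParentalAgeModel) -> tuple[np.ndarray, np.ndarray]:
    ages = np.arange(m.age_min, m.age_max + 1)
    w = np.exp(-0.5 * ((ages - m.mother_mean) / m.mother_sd) ** 2)
    return ages, w / w.sum()


def _offset_distribution(m: ParentalAgeModel) -> tuple[np.ndarray, np.ndarray]:
    lo = int(math.floor(m.offset_mean - 5 * m.offset_sd))
    hi = int(math.ceil(m.offset_mean + 5 * m.offset_sd))
    offs = np.arange(lo, hi + 1)
    w = np.exp(-0.5 * ((offs - m.offset_mean) / m.offset_sd) ** 2)
    return offs, w / w.sum()


def _age_bands(m: ParentalAgeModel) -> list[tuple[int, int]]:
    bands = []
    lo = m.age_min
    while lo <= m.age_max:
        hi = min(lo + 5, m.age_max + 1)
        bands.append((lo, hi))
        lo = hi
    return bands


def _parental_crosstab(m: ParentalAgeModel) -> dict[tuple[tuple[int, int], tuple[int, int]], float]:
    """Exact joint distribution over (father band, mother band)."""
    mothers, pm = _mother_distribution(m)
    offsets, pd_ = _offset_distribution(m)
    fathers = np.clip(mothers[:, None] + offsets[None, :], m.age_min, m.age_max)
    joint = pm[:, None] * pd_[None, :]
    bands = _age_bands(m)

    def band_of(age: int) -> tuple[int, int]:
        for b in bands:
            if b[0] <= age < b[1]:
                return b
        raise AssertionError(age)

    table: dict = {}
    for i, mother in enumerate(mothers):
        mb = band_of(int(mother))
        for j in range(len(offsets)):
            fb = band_of(int(fathers[i, j]))
            table[(fb, mb)] = table.get((fb, mb), 0.0) + float(joint[i, j])
    total = sum(table.values())
    return {k: v / total for k, v in table.items()}


def _rank_distribution(sib: Sequence[float], pool_rank: int = POOL_RANK) -> tuple[float, ...]:
    """Population rank distribution implied by the sibship-size distribution
    with rank uniform within sibship: P(r) = sum_{s >= r} p_s / s."""
    sib = np.asarray(sib, dtype=float)
    probs = np.array([sum(sib[s - 1] / s for s in range(r, len(sib) + 1)) for r in range(1, len(sib) + 1)])
    if len(probs) > pool_rank:
        probs = np.concatenate([probs[: pool_rank - 1], [probs[pool_rank - 1 :].sum()]])
    return tuple(probs / probs.sum())


def _urban_at(year: np.ndarray | int, config: SyntheticConfig) -> np.ndarray | float:
    lo, hi = config.birth_year_range
    p0, p1 = config.urban_trend
    if hi == lo:
        return p0
    frac = (np.asarray(year) - lo) / (hi - lo)
    return p0 + (p1 - p0) * frac


def reference_tables(config: SyntheticConfig) -> dict[str, PopulationReference]:
    """The exact reference tables implied by the generator parameters."""
    grid = [y for y in CENSUS_GRID if config.birth_year_range[0] <= y <= config.birth_year_range[1]]
    if not grid:
        grid = [sum(config.birth_year_range) // 2]
    pgrid = [y for y in PARENTAL_GRID if config.birth_year_range[0] <= y <= config.birth_year_range[1]] or grid
    shares = tuple(config.monthly_probs)
    crosstab = _parental_crosstab(config.parental_age_model)
    return {
        "seasonality": PopulationReference(
            factor="seasonality",
            kind=ReferenceKind.monthly_shares_by_year,
            year_grid=tuple(grid),
            payload={y: shares for y in grid},
        ),
        "urbanicity": PopulationReference(
            factor="urbanicity",
            kind=ReferenceKind.scalar_proportion_by_year,
            year_grid=tuple(grid),
            payload={y: float(_urban_at(y, config)) for y in grid},
        ),
        "paternal_age": PopulationReference(
            factor="paternal_age",
            kind=ReferenceKind.parental_age_crosstab_by_year,
            year_grid=tuple(pgrid),
            payload={y: crosstab for y in pgrid},
        ),
        "migration": PopulationReference(
            factor="migration",
            kind=ReferenceKind.scalar_proportion_by_year,
            year_grid=(1954,),
            payload={1954: config.p_born_abroad},
        ),
        "birth_rank": PopulationReference(
            factor="birth_rank",
            kind=ReferenceKind.rank_distribution,
            year_grid=(0,),
            payload={"ranks": _rank_distribution(config.sibship_size_distribution)},
        ),
    }


def generate_population(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, PopulationReference]]:
    """Draw the pseudo-population and return it with its exact references."""
    rng = np.random.default_rng(config.seed)
    n = config.n_population
    lo, hi = config.birth_year_range

    birth_year = rng.integers(lo, hi + 1, size=n)
    birth_month = rng.choice(np.arange(1, 13), size=n, p=config.monthly_probs)
    male = rng.random(n) < config.p_male
    urban = rng.random(n) < _urban_at(birth_year, config)
    m = config.parental_age_model
    mothers, pm = _mother_distribution(m)
    maternal_age = rng.choice(mothers, size=n, p=pm)
    offsets, pd_ = _offset_distribution(m)
    paternal_age = np.clip(maternal_age + rng.choice(offsets, size=n, p=pd_), m.age_min, m.age_max)
    born_abroad = rng.random(n) < config.p_born_abroad
    sizes = np.arange(1, len(config.sibship_size_distribution) + 1)
    sibship_size = rng.choice(sizes, size=n, p=np.asarray(config.sibship_size_distribution))
    birth_rank = rng.integers(1, sibship_size + 1)

    df = pd.DataFrame(
        {
            "subject_id": [f"P{i:07d}" for i in range(n)],
            "sex": np.where(male, "male", "female"),
            "birth_year": birth_year.astype(int),
            "birth_month": birth_month.astype(int),
            "urban_birth": urban,
            "born_abroad": born_abroad,
            "paternal_age": paternal_age.astype(int),
            "maternal_age": maternal_age.astype(int),
            "birth_rank": birth_rank.astype(int),
            "sibship_size": sibship_size.astype(int),
        }
    )
    return df, reference_tables(config)


def _linear_predictor(df: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    coefs = config.selection_log_odds
    eta = np.zeros(len(df))
    if coefs.get("seasonality"):
        eta += coefs["seasonality"] * df["birth_month"].isin([12, 1, 2, 3]).to_numpy()
    if coefs.get("urbanicity"):
        eta += coefs["urbanicity"] * df["urban_birth"].to_numpy()
    if coefs.get("paternal_age"):
        eta += coefs["paternal_age"] * (df["paternal_age"].to_numpy() >= 35)
    if coefs.get("migration"):
        eta += coefs["migration"] * df["born_abroad"].to_numpy()
    if coefs.get("first_born"):
        eta += coefs["first_born"] * (df["birth_rank"].to_numpy() == 1)
    if coefs.get("maternal_age"):
        eta += coefs["maternal_age"] * (df["maternal_age"].to_numpy() >= 35)
    return eta


def _calibrate_intercept(eta: np.ndarray, target: int) -> float:
    """Bisection for the intercept putting the expected case count at target."""
    if target >= len(eta):
        raise ValueError(f"n_cases_target={target} unattainable with {len(eta)} eligible males")

    def expected(c: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(c + eta)))).sum())

    lo, hi = -40.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def select_cases(population: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Logistic selection of the case sample among males.

    Selection probability is logistic(intercept + sum coef * exposure); the
    intercept is calibrated so the expected sample size equals
    ``n_cases_target``. Females are never selected (the analyses are
    restricted to men). Selection draws continue the generator stream of
    :func:`generate_population` when the same rng is threaded through; for
    reproducibility from the config alone, a fresh stream seeded with
    ``seed + 1`` is used.
    """
    males = population[population["sex"] == "male"]
    eta = _linear_predictor(males, config)
    intercept = _calibrate_intercept(eta, config.n_cases_target)
    p = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    rng = np.random.default_rng(config.seed + 1)
    selected = rng.random(len(males)) < p
    return males[selected].reset_index(drop=True)


def to_case_records(df: pd.DataFrame) -> list[CaseRecord]:
    """Case DataFrame rows as validated :class:`CaseRecord` objects."""
    records = []
    for row in df.to_dict(orient="records"):
        records.append(
            CaseRecord(
                subject_id=str(row["subject_id"]),
                sex=row["sex"],
                birth_year=int(row["birth_year"]),
                birth_month=int(row["birth_month"]) if row.get("birth_month") is not None else None,
                urban_birth=bool(row["urban_birth"]) if row.get("urban_birth") is not None else None,
                born_abroad=bool(row["born_abroad"]) if row.get("born_abroad") is not None else None,
                paternal_age=int(row["paternal_age"]) if row.get("paternal_age") is not None else None,
                maternal_age=int(row["maternal_age"]) if row.get("maternal_age") is not None else None,
                birth_rank=int(row["birth_rank"]) if row.get("birth_rank") is not None else None,
                sibship_size=int(row["sibship_size"]) if row.get("sibship_size") is not None else None,
            )
        )
    return records
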