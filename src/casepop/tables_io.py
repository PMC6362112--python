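"""Data model, CSV readers/writers and validation for case and reference tables.

The pipeline compares a sample of cases (here: exceptional achievers from a
historical survey) against general-population denominators summarised by
official statistics. Two kinds of table flow through it:

* a **case table** — one row per subject, with the demographic fields any
  subset of the five factor analyses needs (fields may be missing per record);
* **population reference tables** — per-census-year exposure summaries: a
  scalar proportion, a 12-vector of monthly birth shares, a paternal x
  maternal 5-year age-band cross-tabulation, or a birth-rank distribution.

All files are UTF-8 CSV with a header row. Column names in case files are
mapped through a user-supplied dialect so archival and synthetic layouts both
load without code changes.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Sex",
    "ReferenceKind",
    "CaseRecord",
    "PopulationReference",
    "ExposureSpec",
    "AssociationResult",
    "TableValidationError",
    "URBAN_THRESHOLD_DEFAULT",
    "read_cases",
    "write_cases",
    "cases_to_frame",
    "read_population_reference",
    "write_population_reference",
    "validate_dataset",
]

#: Historical census definition of an urban birthplace: a town of at least
#: 2000 inhabitants.
URBAN_THRESHOLD_DEFAULT = 2000

_AGE_LO, _AGE_HI = 12, 80  # validation bounds for parental ages, years


class TableValidationError(ValueError):
    """A table violated an invariant; message names the offending row/field."""


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class ReferenceKind(str, enum.Enum):
    scalar_proportion_by_year = "scalar_proportion_by_year"
    monthly_shares_by_year = "monthly_shares_by_year"
    parental_age_crosstab_by_year = "parental_age_crosstab_by_year"
    rank_distribution = "rank_distribution"


class CaseRecord(BaseModel):
    """One case subject; optional fields are ``None`` when not recorded."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    subject_id: str
    sex: Sex
    birth_year: int
    birth_month: Optional[int] = Field(default=None, ge=1, le=12)
    urban_birth: Optional[bool] = None
    birthplace_population: Optional[int] = Field(default=None, ge=0)
    born_abroad: Optional[bool] = None
    paternal_age: Optional[int] = Field(default=None, ge=_AGE_LO, le=_AGE_HI)
    maternal_age: Optional[int] = Field(default=None, ge=_AGE_LO, le=_AGE_HI)
    birth_rank: Optional[int] = Field(default=None, ge=1)
    sibship_size: Optional[int] = Field(default=None, ge=1)

    @model_validator(mode="after")
    def _cross_field(self) -> "CaseRecord":
        if (
            self.birth_rank is not None
            and self.sibship_size is not None
            and self.birth_rank > self.sibship_size
        ):
            raise ValueError(
                f"birth_rank={self.birth_rank} exceeds sibship_size={self.sibship_size}"
            )
        if self.urban_birth is not None and self.birthplace_population is not None:
            implied = self.birthplace_population >= URBAN_THRESHOLD_DEFAULT
            if self.urban_birth != implied:
                raise ValueError(
                    "urban_birth flag inconsistent with birthplace_population "
                    f"({self.birthplace_population}) at threshold {URBAN_THRESHOLD_DEFAULT}"
                )
        return self


class PopulationReference(BaseModel):
    """Per-census-year exposure data for one factor.

    ``payload`` maps each grid year to, depending on ``kind``:

    * a proportion in [0, 1];
    * a 12-vector of monthly birth shares summing to 1;
    * a nested mapping ``{(father_band, mother_band): share}`` where each band
      is a half-open ``(low, high)`` age interval and shares sum to 1;
    * (rank_distribution) a vector over ranks 1..R, the last bin pooling
      "R or more".
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    factor: str
    kind: ReferenceKind
    year_grid: tuple[int, ...]
    payload: dict

    @model_validator(mode="after")
    def _check(self) -> "PopulationReference":
        grid = self.year_grid
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError(f"year_grid must be strictly increasing, got {grid}")
        # printed-precision tables (2-decimal percent shares) can be off 1
        # by a few parts in a thousand after dividing by 100; admit that
        tol = 5e-3
        if self.kind is ReferenceKind.rank_distribution:
            vec = np.asarray(self.payload["ranks"], dtype=float)
            _check_prob_vector(vec, "rank distribution", tol=tol)
            return self
        if set(self.payload) != set(grid):
            raise ValueError("payload years must match year_grid")
        for year, entry in self.payload.items():
            if self.kind is ReferenceKind.scalar_proportion_by_year:
                if not 0.0 <= float(entry) <= 1.0:
                    raise ValueError(f"proportion for {year} outside [0,1]: {entry}")
            elif self.kind is ReferenceKind.monthly_shares_by_year:
                vec = np.asarray(entry, dtype=float)
                if vec.shape != (12,):
                    raise ValueError(f"monthly shares for {year} must have 12 entries")
                _check_prob_vector(vec, f"monthly shares for {year}", tol=tol)
            elif self.kind is ReferenceKind.parental_age_crosstab_by_year:
                _check_crosstab(entry, year, tol=tol)
        return self


def _check_prob_vector(vec: np.ndarray, what: str, tol: float = 1e-6) -> None:
    if np.any(vec < 0):
        raise ValueError(f"{what} has negative entries")
    if not math.isclose(float(vec.sum()), 1.0, abs_tol=max(tol, 1e-6)):
        raise ValueError(f"{what} sums to {vec.sum():.6f}, expected 1")


def _check_crosstab(entry: Mapping, year: int, tol: float = 1e-6) -> None:
    total = 0.0
    father_bands = set()
    for (fb, mb), share in entry.items():
        for band in (fb, mb):
            lo, hi = band
            if hi <= lo:
                raise ValueError(f"band {band} in {year} is empty or inverted")
        father_bands.add(tuple(fb))
        if share < 0:
            raise ValueError(f"negative share in crosstab for {year}")
        total += share
    for bands in (sorted(father_bands), sorted({tuple(mb) for (_, mb) in entry})):
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if lo2 < hi1:
                raise ValueError(
                    f"overlapping age bands {lo1}-{hi1} and {lo2}-{hi2} in {year}"
                )
    if not math.isclose(total, 1.0, abs_tol=max(tol, 1e-6)):
        raise ValueError(f"crosstab for {year} sums to {total:.6f}, expected 1")


class ExposureSpec(BaseModel):
    """Definition of one exposure plus its sample-restriction rules.

    The five built-in factors (see :mod:`casepop.exposure`) instantiate this
    with the study's definitions: December-March births, paternal age >= 35,
    birthplace of >= 2000 inhabitants, born abroad, first-born.
    """

    model_config = ConfigDict(frozen=True)

    factor: str
    month_window: Optional[frozenset[int]] = None
    paternal_age_threshold: Optional[int] = Field(default=None, gt=0)
    urban_threshold: Optional[int] = Field(default=None, gt=0)
    abroad_flag: bool = False
    rank_target: Optional[int] = Field(default=None, gt=0)
    restrict_sex: Optional[Sex] = Sex.male
    restrict_birth_years: Optional[tuple[int, int]] = None
    min_age_at_reference: Optional[int] = None
    reference_year: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ExposureSpec":
        if self.month_window is not None and not self.month_window <= frozenset(range(1, 13)):
            raise ValueError("month_window must be a subset of 1..12")
        if self.min_age_at_reference is not None and self.reference_year is None:
            raise ValueError("min_age_at_reference requires reference_year")
        return self


class AssociationResult(BaseModel):
    """One row of the final report: counts, percentages, OR and 95% CI."""

    model_config = ConfigDict(frozen=True)

    factor: str
    n_exposed_cases: int = Field(ge=0)
    n_cases: int = Field(ge=0)
    pct_exposed_cases: float
    pct_exposed_population: float
    odds_ratio: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)
    p_value: Optional[float] = None
    adjusted_for: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "AssociationResult":
        if self.n_exposed_cases > self.n_cases:
            raise ValueError("n_exposed_cases exceeds n_cases")
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI does not bracket the odds ratio")
        return self


# ---------------------------------------------------------------------------
# Case table I/O

_CASE_COLUMNS = [
    "subject_id",
    "sex",
    "birth_year",
    "birth_month",
    "urban_birth",
    "birthplace_population",
    "born_abroad",
    "paternal_age",
    "maternal_age",
    "birth_rank",
    "sibship_size",
]
_REQUIRED = ("subject_id", "sex", "birth_year")
_INT_FIELDS = (
    "birth_year",
    "birth_month",
    "birthplace_population",
    "paternal_age",
    "maternal_age",
    "birth_rank",
    "sibship_size",
)
_BOOL_FIELDS = ("urban_birth", "born_abroad")
_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def read_cases(path, dialect: Optional[Mapping[str, str]] = None) -> list[CaseRecord]:
    """Read a case table; ``dialect`` maps file column names to canonical ones.

    Missing optional cells become ``None``, never silent zeros. Malformed
    values raise :class:`TableValidationError` naming the row and field;
    duplicate subject ids are an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TableValidationError(f"case table missing required columns: {missing}")
    records: list[CaseRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.to_dict(orient="records")):
        fields: dict = {}
        for col in _CASE_COLUMNS:
            raw = str(row.get(col, "")).strip()
            if raw == "":
                continue
            if col in _INT_FIELDS:
                try:
                    fields[col] = int(float(raw))
                except ValueError:
                    raise TableValidationError(
                        f"row {idx}: field {col!r}: cannot parse {raw!r} as integer"
                    ) from None
            elif col in _BOOL_FIELDS:
                low = raw.lower()
                if low in _TRUE:
                    fields[col] = True
                elif low in _FALSE:
                    fields[col] = False
                else:
                    raise TableValidationError(
                        f"row {idx}: field {col!r}: cannot parse {raw!r} as boolean"
                    )
            else:
                fields[col] = raw
        try:
            rec = CaseRecord(**fields)
        except Exception as exc:
            raise TableValidationError(f"row {idx}: {exc}") from None
        if rec.subject_id in seen:
            raise TableValidationError(f"row {idx}: duplicate subject_id {rec.subject_id!r}")
        seen.add(rec.subject_id)
        records.append(rec)
    return records


def cases_to_frame(records: Sequence[CaseRecord]) -> pd.DataFrame:
    """Case records as a DataFrame with pandas nullable dtypes."""
    df = pd.DataFrame([r.model_dump() for r in records], columns=_CASE_COLUMNS)
    df["sex"] = df["sex"].map(lambda s: s.value if isinstance(s, Sex) else s)
    for col in _INT_FIELDS:
        df[col] = df[col].astype("Int64")
    for col in _BOOL_FIELDS:
        df[col] = df[col].astype("boolean")
    return df


def write_cases(records: Sequence[CaseRecord], path) -> None:
    """Write case records as CSV; ``None`` becomes an empty cell."""
    df = cases_to_frame(records)
    for col in _BOOL_FIELDS:  # stable lower-case text round-trips through read_cases
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(bool(v)).lower())
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Reference table I/O

_MONTH_COLS = [f"m{m:02d}" for m in range(1, 13)]


def _percent_or_fraction(total: float, what: str) -> float:
    """Return the divisor implied by the dialect of a share vector.

    Sums in [95, 105] are the percent dialect, [0.95, 1.05] fractions; anything
    else is an error. Applying the rule to an already-fraction table is a
    no-op (idempotent).
    """
    if 95.0 <= total <= 105.0:
        return 100.0
    if 0.95 <= total <= 1.05:
        return 1.0
    raise TableValidationError(
        f"{what}: shares sum to {total:g}, neither ~1 (fractions) nor ~100 (percent)"
    )


def parse_band(text: str) -> tuple[int, int]:
    """Parse an age-band label into a half-open [low, high) interval.

    Accepts ``"35-39"`` (ages 35..39 -> [35, 40)), ``"<25"`` and ``">50"``
    / ``">=50"`` open-ended labels (closed at the validation bounds).
    """
    t = str(text).strip().replace("–", "-")
    if t.startswith("<"):
        return (_AGE_LO, int(t[1:].lstrip("=")))
    if t.startswith(">"):
        rest = t[1:]
        if rest.startswith("="):
            return (int(rest[1:]), _AGE_HI + 1)
        return (int(rest) + 1, _AGE_HI + 1)
    lo, hi = t.split("-")
    return (int(lo), int(hi) + 1)


def format_band(band: tuple[int, int]) -> str:
    lo, hi = band
    if lo <= _AGE_LO:
        return f"<{hi}"
    if hi > _AGE_HI:
        return f">={lo}"
    return f"{lo}-{hi - 1}"


def read_population_reference(path, factor: str, kind: ReferenceKind | str) -> PopulationReference:
    """Read one reference CSV whose layout matches ``kind``.

    Percent-dialect tables (shares summing to ~100) are renormalised to
    fractions; a grid that is not strictly increasing, or shares summing to
    neither ~1 nor ~100, raise :class:`TableValidationError`.
    """
    kind = ReferenceKind(kind)
    df = pd.read_csv(path)
    try:
        if kind is ReferenceKind.scalar_proportion_by_year:
            years = [int(y) for y in df["year"]]
            values = [float(v) for v in df["proportion"]]
            if any(v > 1.0 for v in values):  # percent dialect for scalar series
                values = [v / 100.0 for v in values]
            payload = dict(zip(years, values))
        elif kind is ReferenceKind.monthly_shares_by_year:
            years = [int(y) for y in df["year"]]
            payload = {}
            for year, (_, row) in zip(years, df.iterrows()):
                vec = np.asarray([float(row[c]) for c in _MONTH_COLS])
                # divide by the dialect's scale only: printed percent rows keep
                # their (rounded) total, so window sums match the tabulation
                vec = vec / _percent_or_fraction(float(vec.sum()), f"monthly shares for {year}")
                payload[year] = tuple(vec)
        elif kind is ReferenceKind.parental_age_crosstab_by_year:
            years = sorted({int(y) for y in df["year"]})
            payload = {}
            for year in years:
                sub = df[df["year"] == year]
                entry = {
                    (parse_band(r["father_band"]), parse_band(r["mother_band"])): float(r["share"])
                    for _, r in sub.iterrows()
                }
                total = sum(entry.values())
                div = _percent_or_fraction(total, f"crosstab for {year}")
                payload[year] = {k: v / div for k, v in entry.items()}
        elif kind is ReferenceKind.rank_distribution:
            ranks = [int(r) for r in df["rank"]]
            if ranks != list(range(1, len(ranks) + 1)):
                raise TableValidationError(f"rank column must be 1..R, got {ranks}")
            vec = np.asarray([float(v) for v in df["share"]])
            vec = vec / _percent_or_fraction(float(vec.sum()), "rank distribution")
            years = [0]
            payload = {"ranks": tuple(vec)}
        else:  # pragma: no cover
            raise AssertionError(kind)
        return PopulationReference(factor=factor, kind=kind, year_grid=tuple(years), payload=payload)
    except (KeyError, ValueError) as exc:
        if isinstance(exc, TableValidationError):
            raise
        raise TableValidationError(f"{path}: {exc}") from None


def write_population_reference(ref: PopulationReference, path) -> None:
    if ref.kind is ReferenceKind.scalar_proportion_by_year:
        df = pd.DataFrame(
            {"year": list(ref.year_grid), "proportion": [ref.payload[y] for y in ref.year_grid]}
        )
    elif ref.kind is ReferenceKind.monthly_shares_by_year:
        rows = []
        for y in ref.year_grid:
            rows.append({"year": y, **{c: v for c, v in zip(_MONTH_COLS, ref.payload[y])}})
        df = pd.DataFrame(rows)
    elif ref.kind is ReferenceKind.parental_age_crosstab_by_year:
        rows = []
        for y in ref.year_grid:
            for (fb, mb), share in sorted(ref.payload[y].items()):
                rows.append(
                    {
                        "year": y,
                        "father_band": format_band(fb),
                        "mother_band": format_band(mb),
                        "share": share,
                    }
                )
        df = pd.DataFrame(rows)
    else:
        vec = ref.payload["ranks"]
        df = pd.DataFrame({"rank": range(1, len(vec) + 1), "share": list(vec)})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset validation report

_FACTOR_FIELDS = {
    "seasonality": ("birth_month",),
    "urbanicity": ("urban_birth", "birthplace_population"),
    "paternal_age": ("paternal_age",),
    "migration": ("born_abroad",),
    "birth_rank": ("birth_rank",),
}


def validate_dataset(
    cases: Sequence[CaseRecord],
    references: Optional[Mapping[str, PopulationReference]] = None,
) -> dict:
    """Report, per factor, how many cases carry the fields that factor needs.

    Each analysis later uses only the records where its variable is present,
    so the per-factor analysable ``n`` differ; this report surfaces them
    before any computation. Purely informational — never raises.
    """
    report: dict = {"n_cases": len(cases), "factors": {}}
    for factor, fields in _FACTOR_FIELDS.items():
        n = sum(1 for r in cases if any(getattr(r, f) is not None for f in fields))
        entry = {"n_with_data": n, "fields": list(fields)}
        if references is not None:
            entry["reference_available"] = factor in references
        report["factors"][factor] = entry
    report["factors"]["birth_rank"]["n_with_sibship"] = sum(
        1 for r in cases if r.birth_rank is not None and r.sibship_size is not None
    )
    return report
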