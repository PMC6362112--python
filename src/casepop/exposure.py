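"""Exposure classification with the study's sample restrictions.

Each case record is classified, per factor, as one of:

* ``exposed`` / ``unexposed`` — eligible and the needed field present;
* ``ineligible`` — excluded by a restriction (sex, birth-year window, or the
  migration age floor);
* ``missing`` — eligible but the field the factor needs is absent.

The five built-in factor definitions follow the study: December-March birth
(the winter-spring excess window from the largest season-of-birth studies of
schizophrenia), paternal age of 35 or more at the subject's birth (inclusive:
the 35-39 band counts as exposed), birth in a town of at least 2000
inhabitants (the historical census urban/rural cut), birth outside France
with the comparison restricted to men aged 35 or more in the reference year,
and being first-born. All analyses are restricted to men; birth-year windows
default to 1879-1913 (1889-1913 for paternal age) to match the census series
the denominators come from.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .tables_io import URBAN_THRESHOLD_DEFAULT, CaseRecord, ExposureSpec, Sex

__all__ = [
    "Status",
    "ExposureCall",
    "builtin_specs",
    "classify",
    "classify_all",
    "exposure_table",
    "WINTER_WINDOW",
    "PATERNAL_AGE_THRESHOLD",
]

#: December-March exposure window.
WINTER_WINDOW = frozenset({12, 1, 2, 3})
#: "35 or more" — inclusive threshold for advanced paternal age.
PATERNAL_AGE_THRESHOLD = 35
#: Reference year for the migration age floor (census year of the denominator).
MIGRATION_REFERENCE_YEAR = 1954

BIRTH_WINDOW_DEFAULT = (1879, 1913)
BIRTH_WINDOW_PATERNAL = (1889, 1913)


class Status(str, enum.Enum):
    exposed = "exposed"
    unexposed = "unexposed"
    ineligible = "ineligible"
    missing = "missing"


class ExposureCall(BaseModel):
    model_config = ConfigDict(frozen=True)

    subject_id: str
    factor: str
    status: Status


def builtin_specs(
    *,
    month_window: Iterable[int] = WINTER_WINDOW,
    paternal_age_threshold: int = PATERNAL_AGE_THRESHOLD,
    urban_threshold: int = URBAN_THRESHOLD_DEFAULT,
    reference_year: int = MIGRATION_REFERENCE_YEAR,
    min_age_at_reference: int = 35,
    birth_window: tuple[int, int] = BIRTH_WINDOW_DEFAULT,
    paternal_birth_window: tuple[int, int] = BIRTH_WINDOW_PATERNAL,
) -> dict[str, ExposureSpec]:
    """The five factor definitions with their default restrictions."""
    return {
        "seasonality": ExposureSpec(
            factor="seasonality",
            month_window=frozenset(month_window),
            restrict_birth_years=birth_window,
        ),
        "urbanicity": ExposureSpec(
            factor="urbanicity",
            urban_threshold=urban_threshold,
            restrict_birth_years=birth_window,
        ),
        "paternal_age": ExposureSpec(
            factor="paternal_age",
            paternal_age_threshold=paternal_age_threshold,
            restrict_birth_years=paternal_birth_window,
        ),
        "migration": ExposureSpec(
            factor="migration",
            abroad_flag=True,
            min_age_at_reference=min_age_at_reference,
            reference_year=reference_year,
        ),
        "birth_rank": ExposureSpec(
            factor="birth_rank",
            rank_target=1,
            restrict_birth_years=birth_window,
        ),
    }


def classify(record: CaseRecord, spec: ExposureSpec) -> ExposureCall:
    """Classify one record for one factor, applying restrictions first."""
    status = _status(record, spec)
    return ExposureCall(subject_id=record.subject_id, factor=spec.factor, status=status)


def _status(record: CaseRecord, spec: ExposureSpec) -> Status:
    if spec.restrict_sex is not None and record.sex != spec.restrict_sex:
        return Status.ineligible
    if spec.restrict_birth_years is not None:
        lo, hi = spec.restrict_birth_years
        if not lo <= record.birth_year <= hi:
            return Status.ineligible
    if spec.min_age_at_reference is not None:
        age = spec.reference_year - record.birth_year
        if age < spec.min_age_at_reference:
            return Status.ineligible

    if spec.month_window is not None:
        if record.birth_month is None:
            return Status.missing
        return Status.exposed if record.birth_month in spec.month_window else Status.unexposed
    if spec.paternal_age_threshold is not None:
        if record.paternal_age is None:
            return Status.missing
        return (
            Status.exposed
            if record.paternal_age >= spec.paternal_age_threshold
            else Status.unexposed
        )
    if spec.urban_threshold is not None:
        # explicit flag wins (consistency with birthplace_population is
        # enforced at read time); fall back to the population-size cut
        if record.urban_birth is not None:
            return Status.exposed if record.urban_birth else Status.unexposed
        if record.birthplace_population is not None:
            return (
                Status.exposed
                if record.birthplace_population >= spec.urban_threshold
                else Status.unexposed
            )
        return Status.missing
    if spec.abroad_flag:
        if record.born_abroad is None:
            return Status.missing
        return Status.exposed if record.born_abroad else Status.unexposed
    if spec.rank_target is not None:
        if record.birth_rank is None:
            return Status.missing
        return Status.exposed if record.birth_rank == spec.rank_target else Status.unexposed
    raise ValueError(f"spec for {spec.factor!r} defines no exposure predicate")


def classify_all(
    cases: Sequence[CaseRecord], specs: Mapping[str, ExposureSpec]
) -> dict[str, list[ExposureCall]]:
    return {name: [classify(r, spec) for r in cases] for name, spec in specs.items()}


def exposure_table(
    cases: Sequence[CaseRecord], specs: Mapping[str, ExposureSpec]
) -> pd.DataFrame:
    """Per-factor exposed counts among eligible, non-missing records.

    Returns a frame with columns ``factor, n_exposed, n_total, pct_exposed``
    (percentage to 2 decimals) plus the ``n_ineligible``/``n_missing``
    bookkeeping columns; a factor with zero eligible records is flagged in
    the ``zero_eligible`` column rather than dropped.
    """
    rows = []
    for name, spec in specs.items():
        statuses = [_status(r, spec) for r in cases]
        n_exp = sum(s is Status.exposed for s in statuses)
        n_unexp = sum(s is Status.unexposed for s in statuses)
        n_inel = sum(s is Status.ineligible for s in statuses)
        n_miss = sum(s is Status.missing for s in statuses)
        n_total = n_exp + n_unexp
        rows.append(
            {
                "factor": name,
                "n_exposed": n_exp,
                "n_total": n_total,
                "pct_exposed": round(100.0 * n_exp / n_total, 2) if n_total else float("nan"),
                "n_ineligible": n_inel,
                "n_missing": n_miss,
                "zero_eligible": n_total == 0,
            }
        )
    return pd.DataFrame(rows)
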