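"""End-to-end analysis driver: restrict, classify, weight, compare.

For each enabled factor the driver classifies the case records, builds the
matching population denominator (secularly weighted for trended series,
external for migration, rank-distribution or within-family null for birth
order) and emits one Table-style association row. Birth rank yields two
rows — against the general-population distribution and against the
within-family null — so a full run over the five factors produces six rows.

The run log records, per factor, the eligible/missing counts, the census
weights used and every threshold, so each reported number can be re-derived
by hand.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import birth_rank_null, denominator as denom, exposure as expo
from .or_stats import Stratum, compute_association
from .tables_io import (
    AssociationResult,
    CaseRecord,
    PopulationReference,
    ReferenceKind,
    read_cases,
    read_population_reference,
)

__all__ = ["CIOptions", "RunConfig", "analyse", "run_pipeline", "report_to_json", "report_to_frame"]

FACTORS = ("seasonality", "urbanicity", "paternal_age", "migration", "birth_rank")


class CIOptions(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    level: float = Field(default=0.95, gt=0, lt=1)
    continuity: bool = False
    adjustment_scheme: str = "woolf"  # or "mantel-haenszel"


class ReferenceSource(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    path: Optional[str] = None
    kind: Optional[str] = None
    proportion: Optional[float] = None  # external scalar (migration)
    label: str = ""


class RunConfig(BaseModel):
    """YAML-backed run configuration; unknown keys are rejected."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    cases: str
    dialect: Optional[dict[str, str]] = None
    references: dict[str, ReferenceSource] = Field(default_factory=dict)
    factors: tuple[str, ...] = FACTORS
    overrides: dict[str, dict] = Field(default_factory=dict)
    ci: CIOptions = CIOptions()
    interpolation: str = "nearest"
    adjust_paternal_for_maternal: bool = True
    log_level: str = "info"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


_DEFAULT_KINDS = {
    "seasonality": ReferenceKind.monthly_shares_by_year,
    "urbanicity": ReferenceKind.scalar_proportion_by_year,
    "paternal_age": ReferenceKind.parental_age_crosstab_by_year,
    "migration": ReferenceKind.scalar_proportion_by_year,
    "birth_rank": ReferenceKind.rank_distribution,
}


def _eligible(cases: Sequence[CaseRecord], spec) -> tuple[list[CaseRecord], dict]:
    exposed, unexposed, n_inel, n_miss = [], [], 0, 0
    for rec in cases:
        status = expo.classify(rec, spec).status
        if status is expo.Status.exposed:
            exposed.append(rec)
        elif status is expo.Status.unexposed:
            unexposed.append(rec)
        elif status is expo.Status.ineligible:
            n_inel += 1
        else:
            n_miss += 1
    counts = {
        "n_exposed": len(exposed),
        "n_unexposed": len(unexposed),
        "n_ineligible": n_inel,
        "n_missing": n_miss,
    }
    return exposed + unexposed, counts


def analyse(
    cases: Sequence[CaseRecord],
    references: Mapping[str, PopulationReference],
    factors: Sequence[str] = FACTORS,
    specs: Optional[Mapping[str, object]] = None,
    migration_proportion: Optional[float] = None,
    ci: CIOptions = CIOptions(),
    interpolation: str = "nearest",
    adjust_paternal_for_maternal: bool = True,
) -> tuple[list[AssociationResult], dict]:
    """Run the enabled factor analyses on in-memory inputs.

    ``references`` supplies one :class:`PopulationReference` per enabled
    factor; migration may instead give ``migration_proportion`` (an external
    estimate such as the 8.1% migrant share of men aged 35+).
    """
    if not factors:
        raise ValueError("no factors enabled")
    specs = dict(specs) if specs is not None else expo.builtin_specs()
    for factor in factors:
        if factor == "migration" and migration_proportion is not None:
            continue
        if factor not in references:
            raise ValueError(f"missing reference table for enabled factor {factor!r}")

    results: list[AssociationResult] = []
    log: dict = {"factors": {}}
    for factor in factors:
        spec = specs[factor]
        flog: dict = {"spec": json.loads(spec.model_dump_json())}
        if factor == "seasonality":
            sample, counts = _eligible(cases, spec)
            flog.update(counts)
            d = denom.monthly_exposure_fraction(
                references[factor],
                spec.month_window,
                [r.birth_year for r in sample],
                interpolation=interpolation,
            )
            results.append(_crude(factor, counts, d, ci))
            flog["denominator"] = _denom_log(d)
        elif factor == "urbanicity":
            sample, counts = _eligible(cases, spec)
            flog.update(counts)
            d = denom.secular_weighting(
                references[factor], [r.birth_year for r in sample], interpolation=interpolation
            )
            results.append(_crude(factor, counts, d, ci))
            flog["denominator"] = _denom_log(d)
        elif factor == "paternal_age":
            res, flog2 = _paternal(
                cases, spec, references[factor], ci, interpolation, adjust_paternal_for_maternal
            )
            flog.update(flog2)
            results.append(res)
        elif factor == "migration":
            sample, counts = _eligible(cases, spec)
            flog.update(counts)
            if migration_proportion is not None:
                d = denom.external_denominator(migration_proportion, "external estimate")
            else:
                ref = references[factor]
                if len(ref.year_grid) == 1:
                    d = denom.external_denominator(
                        float(ref.payload[ref.year_grid[0]]), "reference table"
                    )
                else:
                    d = denom.secular_weighting(
                        ref, [r.birth_year for r in sample], interpolation=interpolation
                    )
            results.append(_crude(factor, counts, d, ci))
            flog["denominator"] = _denom_log(d)
        elif factor == "birth_rank":
            res_pair, flog2 = _birth_rank(cases, spec, references[factor], ci)
            flog.update(flog2)
            results.extend(res_pair)
        else:
            raise ValueError(f"unknown factor {factor!r}")
        log["factors"][factor] = flog
    return results, log


def _denom_log(d: denom.WeightedDenominator) -> dict:
    entry = {
        "exposed_proportion": d.exposed_proportion,
        "provenance": d.provenance,
        "weights": {str(y): w for y, w in d.weights_used.items()},
    }
    if d.strata:
        entry["strata"] = dict(d.strata)
    return entry


def _crude(factor, counts, d, ci: CIOptions) -> AssociationResult:
    a, b = counts["n_exposed"], counts["n_unexposed"]
    if a + b == 0:
        raise ValueError(f"factor {factor!r}: zero eligible records")
    return compute_association(
        factor, a, b, d, level=ci.level, continuity=ci.continuity
    )


def _paternal(cases, spec, reference, ci: CIOptions, interpolation, adjust):
    sample, counts = _eligible(cases, spec)
    flog = dict(counts)
    d = denom.parental_age_exposure(
        reference,
        spec.paternal_age_threshold,
        [r.birth_year for r in sample],
        interpolation=interpolation,
    )
    flog["denominator"] = _denom_log(d)
    threshold = spec.paternal_age_threshold
    with_maternal = [r for r in sample if r.maternal_age is not None]
    if adjust and with_maternal and d.strata:
        # adjusted analysis restricted to records carrying both parental ages,
        # so the stratum counts sum to the margins it reports
        strata = []
        for name, keep in (
            ("mother_lt", lambda r: r.maternal_age < threshold),
            ("mother_ge", lambda r: r.maternal_age >= threshold),
        ):
            sub = [r for r in with_maternal if keep(r)]
            a_i = sum(1 for r in sub if r.paternal_age >= threshold)
            b_i = len(sub) - a_i
            if a_i >= 1 and b_i >= 1:
                strata.append(Stratum(a=a_i, b=b_i, p_pop=d.strata[name], name=name))
        if len(strata) >= 1 and sum(s.a + s.b for s in strata) == len(with_maternal):
            flog["strata"] = [
                {"name": s.name, "a": s.a, "b": s.b, "p_pop": s.p_pop} for s in strata
            ]
            res = compute_association(
                "paternal_age",
                sum(s.a for s in strata),
                sum(s.b for s in strata),
                d,
                strata=strata,
                level=ci.level,
                continuity=ci.continuity,
                adjustment_scheme=ci.adjustment_scheme,
                adjusted_for=("maternal_age",),
            )
            return res, flog
    return _crude("paternal_age", counts, d, ci), flog


def _birth_rank(cases, spec, reference, ci: CIOptions):
    sample, counts = _eligible(cases, spec)
    flog = dict(counts)
    a = sum(1 for r in sample if r.birth_rank == spec.rank_target)
    b = len(sample) - a
    pop_dist = birth_rank_null.from_reference(reference)
    d_pop = denom.WeightedDenominator(
        factor="birth_rank",
        exposed_proportion=birth_rank_null.first_born_fraction(pop_dist),
        weights_used={},
        provenance="unweighted",
    )
    res_pop = compute_association(
        "first_born_vs_population", a, b, d_pop, level=ci.level, continuity=ci.continuity
    )

    # within-family comparison: only records whose sibship size is known can
    # enter either side of it
    with_sib = [r for r in sample if r.sibship_size is not None]
    flog["n_with_sibship"] = len(with_sib)
    if not with_sib:
        raise ValueError("within-family birth-rank comparison: no sibship sizes available")
    null = birth_rank_null.within_family_null([r.sibship_size for r in with_sib])
    a_f = sum(1 for r in with_sib if r.birth_rank == spec.rank_target)
    b_f = len(with_sib) - a_f
    d_fam = denom.WeightedDenominator(
        factor="birth_rank",
        exposed_proportion=birth_rank_null.first_born_fraction(null),
        weights_used={},
        provenance="unweighted",
    )
    res_fam = compute_association(
        "first_born_within_family", a_f, b_f, d_fam, level=ci.level, continuity=ci.continuity
    )
    flog["within_family_null_first_born"] = d_fam.exposed_proportion
    flog["population_first_born"] = d_pop.exposed_proportion
    return [res_pop, res_fam], flog


def run_pipeline(config: RunConfig) -> tuple[list[AssociationResult], dict]:
    """File-based entry point: load tables per config, then :func:`analyse`."""
    for name, src in config.references.items():
        if src.path is not None and not Path(src.path).exists():
            raise FileNotFoundError(f"reference table for {name!r} not found: {src.path}")
    if not Path(config.cases).exists():
        raise FileNotFoundError(f"case table not found: {config.cases}")

    cases = read_cases(config.cases, dialect=config.dialect)
    references: dict[str, PopulationReference] = {}
    migration_proportion = None
    for name, src in config.references.items():
        if src.proportion is not None:
            if name != "migration":
                raise ValueError(f"scalar proportion shortcut only supported for migration, not {name!r}")
            migration_proportion = src.proportion
            continue
        kind = src.kind or _DEFAULT_KINDS[name].value
        references[name] = read_population_reference(src.path, name, kind)

    specs = expo.builtin_specs()
    for name, over in config.overrides.items():
        base = specs[name].model_dump()
        base.update(over)
        specs[name] = type(specs[name])(**base)

    results, log = analyse(
        cases,
        references,
        factors=config.factors,
        specs=specs,
        migration_proportion=migration_proportion,
        ci=config.ci,
        interpolation=config.interpolation,
        adjust_paternal_for_maternal=config.adjust_paternal_for_maternal,
    )
    log["n_cases_read"] = len(cases)
    return results, log


def report_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": r.factor,
                "n_exposed": r.n_exposed_cases,
                "n": r.n_cases,
                "pct_cases": r.pct_exposed_cases,
                "pct_pop": r.pct_exposed_population,
                "or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "adjusted_for": ";".join(r.adjusted_for),
            }
            for r in results
        ]
    )


def report_to_json(results: Sequence[AssociationResult], log: Optional[dict] = None) -> str:
    """Canonical JSON report; deterministic for identical inputs."""
    payload = {"results": [json.loads(r.model_dump_json()) for r in results]}
    if log is not None:
        payload["log"] = log
    return json.dumps(payload, indent=2, sort_keys=True)
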