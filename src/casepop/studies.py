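"""Simulation studies over the synthetic generator.

Two canned studies summarise how well the pipeline recovers known truth:

* **parameter recovery** — generate a pseudo-population with non-null
  selection odds ratios, run the full pipeline, and compare each factor's
  estimated case-population OR (and its 95% CI) with the true selection OR;
  in the rare-outcome regime the two coincide up to sampling noise.
* **null calibration** — with all selection coefficients at zero, the 95%
  intervals should cover OR = 1 for about 95% of independent replicates.

Both return tidy per-replicate frames so tests and drivers can summarise
them however they need.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .pipeline import CIOptions, analyse
from .synthetic import SyntheticConfig, generate_population, select_cases, to_case_records

__all__ = [
    "run_synthetic_analysis",
    "parameter_recovery",
    "null_calibration",
    "RECOVERY_TRUE_ORS",
]

#: Selection odds ratios for the recovery study: strong urbanicity and
#: first-born effects, a modest paternal-age one, the rest null.
RECOVERY_TRUE_ORS: dict[str, float] = {
    "first_born": 2.0,
    "urbanicity": 3.0,
    "paternal_age": 1.2,
    "seasonality": 1.0,
    "migration": 1.0,
}

#: Report row that estimates each selection factor.
FACTOR_TO_ROW = {
    "seasonality": "seasonality",
    "urbanicity": "urbanicity",
    "paternal_age": "paternal_age",
    "migration": "migration",
    "first_born": "first_born_vs_population",
}


def run_synthetic_analysis(config: SyntheticConfig, ci: Optional[CIOptions] = None):
    """Generate, select and analyse one synthetic replicate."""
    population, references = generate_population(config)
    cases = select_cases(population, config)
    records = to_case_records(cases)
    return analyse(records, references, ci=ci or CIOptions())


def _one_replicate(config: SyntheticConfig, true_ors: Mapping[str, float]) -> list[dict]:
    results, _ = run_synthetic_analysis(config)
    by_row = {r.factor: r for r in results}
    rows = []
    for factor, truth in true_ors.items():
        r = by_row[FACTOR_TO_ROW[factor]]
        rows.append(
            {
                "seed": config.seed,
                "factor": factor,
                "true_or": truth,
                "or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "covered": bool(r.ci_low <= truth <= r.ci_high),
                "n_cases": r.n_cases,
            }
        )
    return rows


def parameter_recovery(
    true_ors: Mapping[str, float] = RECOVERY_TRUE_ORS,
    n_population: int = 200_000,
    n_cases_target: int = 2000,
    seeds: Sequence[int] = tuple(range(100, 110)),
) -> pd.DataFrame:
    """Per-seed OR estimates against the true selection odds ratios."""
    import math

    rows = []
    for seed in seeds:
        config = SyntheticConfig(
            seed=seed,
            n_population=n_population,
            n_cases_target=n_cases_target,
            selection_log_odds={k: math.log(v) for k, v in true_ors.items()},
        )
        rows.extend(_one_replicate(config, true_ors))
    return pd.DataFrame(rows)


def null_calibration(
    n_seeds: int = 200,
    n_population: int = 60_000,
    n_cases_target: int = 800,
    base_seed: int = 1000,
) -> pd.DataFrame:
    """Coverage of OR = 1 under the all-null selection model."""
    null_ors = {k: 1.0 for k in RECOVERY_TRUE_ORS}
    rows = []
    for i in range(n_seeds):
        config = SyntheticConfig(
            seed=base_seed + i,
            n_population=n_population,
            n_cases_target=n_cases_target,
        )
        rows.extend(_one_replicate(config, null_ors))
    return pd.DataFrame(rows)


def coverage_summary(replicates: pd.DataFrame) -> pd.DataFrame:
    """Per-factor coverage rate and mean estimate across replicates."""
    return (
        replicates.groupby("factor")
        .agg(
            coverage=("covered", "mean"),
            mean_or=("or", "mean"),
            true_or=("true_or", "first"),
            n_runs=("seed", "count"),
        )
        .reset_index()
    )
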