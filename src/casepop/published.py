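"""Re-derivation of the published comparison table from its printed marginals.

The original 1957 survey file is archival and not redistributable, but the
published study prints enough marginal information — per-factor exposed
counts and percentages, pooled monthly birth shares, birth-rank
distributions, the paternal 5-year age bands and the external migrant share
of men aged 35+ (8.1%) — to re-derive the case-population odds ratios and
their fixed-denominator Woolf intervals. This module ships those printed
marginals as package data and runs the pipeline's own primitives over them.

Where printed counts and percentages disagree (the migration and first-born
rows), the percentages are authoritative: the published odds ratios
reproduce from the percentages, not from the counts. Case-side cell counts
for the intervals are therefore reconstructed as round(pct x n).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .birth_rank_null import first_born_fraction, from_reference
from .denominator import external_denominator, monthly_exposure_fraction
from .exposure import WINTER_WINDOW
from .or_stats import odds_ratio, woolf_ci_fixed_denominator
from .tables_io import ReferenceKind, parse_band, read_population_reference

__all__ = ["published_path", "load_exposure_counts", "reproduce_published"]

#: Migrant share of men aged 35 or more living in France in 1954 — an
#: external estimate combined from census and public statistics, used as a
#: passthrough input.
MIGRANT_SHARE_1954 = 0.081

#: Seasonality case sample size (month of birth collected separately from
#: the survey file, so its n differs from the other analyses).
N_SEASONALITY_CASES = 2255


def published_path(name: str):
    return resources.files("casepop").joinpath("data", "published", name)


def load_exposure_counts() -> pd.DataFrame:
    with resources.as_file(published_path("achiever_exposure_counts.csv")) as p:
        return pd.read_csv(p)


def _rank_reference(name: str):
    with resources.as_file(published_path(name)) as p:
        return read_population_reference(p, "birth_rank", ReferenceKind.rank_distribution)


def _counts_from_pct(pct: float, n: int) -> tuple[int, int]:
    a = round(pct / 100.0 * n)
    return a, n - a


def reproduce_published() -> dict:
    """Recompute the headline quantities from the printed marginals.

    Returns a flat mapping of descriptive names to ``{"value", "n"}``
    entries, values on the printed scale (percent as 91.2-style numbers,
    odds ratios as plain ratios, all at full precision — round for display).
    """
    out: dict[str, dict] = {}

    # December-March exposure aggregates from the pooled monthly shares
    for side, fname, n in (
        ("achievers", "monthly_shares_achievers.csv", N_SEASONALITY_CASES),
        ("population", "monthly_shares_population.csv", 0),
    ):
        with resources.as_file(published_path(fname)) as p:
            ref = read_population_reference(p, "seasonality", ReferenceKind.monthly_shares_by_year)
        frac = monthly_exposure_fraction(ref, WINTER_WINDOW).exposed_proportion
        out[f"winter_birth_pct_{side}"] = {"value": 100.0 * frac, "n": n}

    # per-factor case exposure percentages from the printed counts
    counts = load_exposure_counts().set_index("factor")
    for factor in ("urbanicity", "paternal_age"):
        row = counts.loc[factor]
        out[f"{factor}_pct_exposed_cases"] = {
            "value": 100.0 * row["n_exposed"] / row["n_total"],
            "n": int(row["n_total"]),
        }

    # population paternal-age marginal from the printed 5-year bands
    with resources.as_file(published_path("father_age_bands_population.csv")) as p:
        bands = pd.read_csv(p)
    exposed = sum(
        float(r["share"]) for _, r in bands.iterrows() if parse_band(r["father_band"])[0] >= 35
    )
    out["paternal_age_pct_population"] = {"value": exposed, "n": 0}

    # first-born odds ratios: cases vs general population and vs the
    # within-family reference; CI from reconstructed case cells
    achievers = from_reference(_rank_reference("rank_distribution_achievers.csv"))
    pop = from_reference(_rank_reference("rank_distribution_population.csv"))
    fam = from_reference(_rank_reference("rank_distribution_achiever_families.csv"))
    p_case = first_born_fraction(achievers)
    n_rank = int(counts.loc["first_born", "n_total"])
    a, b = _counts_from_pct(float(counts.loc["first_born", "pct_printed"]), n_rank)

    or_pop = odds_ratio(p_case, first_born_fraction(pop))
    lo, hi = woolf_ci_fixed_denominator(a, b, or_pop)
    out["first_born_or_vs_population"] = {"value": or_pop, "n": n_rank}
    out["first_born_ci_low"] = {"value": lo, "n": n_rank}
    out["first_born_ci_high"] = {"value": hi, "n": n_rank}

    or_fam = odds_ratio(p_case, first_born_fraction(fam))
    out["first_born_or_within_family"] = {"value": or_fam, "n": n_rank}

    # migration: printed case percentage vs the external 1954 estimate
    mig = counts.loc["migration"]
    n_mig = int(mig["n_total"])
    p_mig = float(mig["pct_printed"]) / 100.0
    d = external_denominator(MIGRANT_SHARE_1954, "men aged 35+, France 1954")
    or_mig = odds_ratio(p_mig, d.exposed_proportion)
    a_m, b_m = _counts_from_pct(float(mig["pct_printed"]), n_mig)
    lo_m, hi_m = woolf_ci_fixed_denominator(a_m, b_m, or_mig)
    out["migration_or"] = {"value": or_mig, "n": n_mig}
    out["migration_ci_low"] = {"value": lo_m, "n": n_mig}
    out["migration_ci_high"] = {"value": hi_m, "n": n_mig}

    return out
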