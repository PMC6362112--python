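# casepop

Case–population odds-ratio analysis for historical epidemiology: compare the
exposure profile of a case sample against general-population denominators
assembled from sparse census series.

The motivating application is a re-analysis of a 1957 survey of exceptional
achievers in France, asking whether demographic factors associated with an
increased risk of schizophrenia — winter–spring birth (December–March),
urban birth (town of ≥ 2000 inhabitants), paternal age ≥ 35 years, migrant
origin, and being first-born — are also associated with the opposite,
exceptionally positive outcome. Because the outcome is rare, the comparison
group is not a sampled control series but the general population summarised
by official statistics (a case–referent design with population denominators).

## The statistic

For each factor, with `a` exposed and `b` unexposed cases and a population
exposed proportion `p` treated as **fixed** (it comes from census
tabulations, not a sample):

```
OR = (a/b) / (p/(1−p))
SE(log OR) = sqrt(1/a + 1/b)            (case-side Woolf variance only)
95% CI = exp(log OR ± 1.959964 · SE)
```

Around that core the package provides:

- **Secular-trend weighting** — per-census-year reference values
  (1881–1911 grid, parental ages from 1892) weighted by the case sample's
  birth-year distribution via nearest-census-year assignment.
- **Within-family birth-rank null** — P(rank = r) = mean over case sibships
  of 1/s for r ≤ s: the rank distribution expected if every sibling were
  equally likely to be the case, removing between-family confounding; ranks
  ≥ 9 pooled.
- **Maternal-age adjustment** — the paternal-age OR stratified on maternal
  age (same 35-year cut) against per-stratum population odds from the
  paternal × maternal age-band cross-tabulation, pooled by inverse-variance
  (Woolf) weights.
- **A seeded synthetic generator** — pseudo-population plus the exact
  reference tables its parameters imply, with logistic case selection whose
  coefficients are log odds ratios, so the whole pipeline is testable
  against known truth.

## Worked example

Generate a synthetic cohort and run all five analyses:

```
casepop generate --config synth.yaml --out-dir data/
casepop run --config data/run_config.yaml --out report.json
```

or, as an analysis sequence, `python analysis/01_generate_cohort.py` then
`python analysis/03_run_synthetic_pipeline.py`, which prints (seed 42,
200k individuals, true ORs: urban 3.0, first-born 2.0, paternal age 1.2):

```
                  factor  n_exposed    n  pct_cases  pct_pop   or  ci_low  ci_high
             seasonality        696 1987      35.03    34.23 1.04    0.94     1.14
              urbanicity       1398 1987      70.36    45.37 2.86    2.60     3.15
            paternal_age        658 1438      45.76    42.27 1.13    1.01     1.27
               migration        167 1987       8.40     8.10 1.04    0.89     1.22
first_born_vs_population       1378 1987      69.35    55.30 1.83    1.66     2.01
first_born_within_family       1378 1987      69.35    62.41 1.36    1.24     1.50
```

Each row is one factor's comparison: exposed case count and percentage, the
(weighted) population exposed percentage, and the OR with its 95% CI. The
three non-null factors are detected with their true values inside the
intervals; the two null factors sit near OR = 1. Birth rank appears twice —
once against the general-population rank distribution, once against the
within-family null (the latter is attenuated because selection acts within
sibships of varying size). The paternal-age row is maternal-age adjusted.

`python analysis/02_reproduce_published.py` re-derives the historical
study's headline numbers from its printed marginal tables (shipped as
package data): first-born OR 2.13 (95% CI 1.95–2.33) against the general
population and 1.21 against the achievers' own families, migration OR 0.94,
December–March birth shares 32.42% (achievers) vs 34.17% (population),
urban exposure 84.28%, paternal age ≥ 35 exposure 35.56%.

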