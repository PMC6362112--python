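# Methods

## Design

The pipeline implements a case–referent comparison in which the referent is
not a sampled control group but the general population summarised by
official statistics. For each factor it proceeds in four stages: restrict
the case sample (sex, birth-year window, age floor), classify each record
as exposed/unexposed, build a single population exposed proportion matched
to the case sample, and form the odds ratio with a confidence interval.
Records are used per analysis: each factor's comparison includes exactly
the eligible records where that factor's variable is non-missing, so the
per-factor `n` differ, mirroring how such survey data arrive.

### Exposure definitions and restrictions

| factor | exposed if | restriction |
|---|---|---|
| seasonality | birth month ∈ {12, 1, 2, 3} | men born 1879–1913 |
| urbanicity | urban flag, or birthplace ≥ 2000 inhabitants | men born 1879–1913 |
| paternal age | father's age at birth ≥ 35 (inclusive — the 35–39 band is exposed) | men born 1889–1913 |
| migration | born abroad | men aged ≥ 35 at the 1954 reference year |
| birth rank | first-born | men born 1879–1913 |

All windows, thresholds and the reference year are configuration
parameters; the defaults above are the study's definitions, dictated by the
available census series (births 1881–1911, parental ages from 1892, the
migrant denominator referring to men over 35 in 1954). An explicit urban
flag takes precedence over a birthplace population size; a record carrying
both inconsistently is rejected at read time.

## Denominator construction

Census references are sparse: one value (or table) per grid year
(1881, 1886, …, 1911; 1892, 1896, 1901, 1906, 1911 for parental ages). A
trended series is reduced to one proportion by weighting each grid year by
the fraction of eligible cases assigned to it, with each case assigned to
its **nearest** grid year (exact ties to the earlier year). Nearest
assignment was chosen over interpolation as the simplest scheme consistent
with a 5-year grid — with birth years uniform over 1879–1913 every interior
grid year collects a symmetric 5-year bin, so a linear trend incurs no
discretisation bias; linear interpolation is available behind
`interpolation: linear` for sensitivity analysis. The weighted proportion
is convex in the per-year inputs and invariant to case ordering.

Monthly shares are used exactly as tabulated, with no correction for
unequal month lengths (the historical tabulations make none). Percent- and
fraction-dialect tables are auto-detected by their row sums (sums in
[95, 105] vs [0.95, 1.05]); percent tables are divided by exactly 100 rather
than rescaled to sum to one, so window aggregates of printed 2-decimal
shares equal the printed sums. Validation therefore admits share-vector
sums within 0.005 of 1 — printed 12-vectors routinely miss 1 by a few parts
per thousand, and rescaling them would silently change the very aggregates
the tables were published to convey.

The migration denominator (8.1% of men aged 35+ living in France in 1954)
is a passthrough external estimate: its source combination of census and
public statistics is not reconstructable, so it enters with
`external_estimate` provenance and contributes no variance.

## Birth-rank references

Two denominators are built. The general-population rank distribution is a
supplied table (historically: the 1931 census, women born 1850–1889 with at
least one child, ranks 1 to "9 or more"). The within-family null is
computed from the cases' own sibship sizes as
P(rank = r) = mean over families of 1/s·1(r ≤ s): if within each sibship
every sibling were equally likely to be the sampled case, this is the rank
distribution the case sample would show, and comparing against it removes
between-family confounding. The uniform-within-sibship formalisation is
this module's core modelling decision; it implies P(r) is non-increasing in
r (enforced as an invariant, with the pooled "9+" bin exempt). A record
missing its sibship size cannot enter either side of the within-family
comparison but is retained in the general-population one.

## Odds ratio and interval

The population proportion is treated as fixed — census denominators are
effectively complete counts, and treating them as sampled would require an
arbitrary pseudo-`n`. Hence SE(log OR) = √(1/a + 1/b) on the case cells
only (a Woolf variance restricted to the case side). z = Φ⁻¹(0.975) =
1.959964 is used internally; reporting is at 2 decimals, computation at
full precision. Zero cells are refused rather than continuity-corrected by
default (corrections would silently change reproduced values); a
Haldane–Anscombe +0.5 correction is available behind a flag. A percentile
bootstrap of the case side (resampling the n exposure indicators, i.e. a
binomial draw of a) provides an independent check of the analytic interval
and agrees within a few percent for cells ≥ 100.

Adjustment (maternal age for the paternal-age factor) stratifies the cases
at the same 35-year cut, takes each stratum's log OR against that stratum's
fixed population odds from the paternal × maternal cross-tabulation, and
pools by inverse-variance weights wᵢ = 1/(1/aᵢ + 1/bᵢ), with pooled
SE = 1/√Σwᵢ. Mantel–Haenszel-style pooling is offered as an alternative
scheme. The adjusted analysis is restricted to records carrying both
parental ages, so its stratum counts sum to the margins it reports; if a
stratum has an empty cell the crude OR is reported instead (and the row is
then not marked adjusted).

## Synthetic generator

The generator emulates the *structure* the analysis assumes, not any
historical cohort: individuals are independent draws with

- birth year uniform on 1879–1913 (the achievers' analysable span);
- birth month multinomial; the default shares are the historical
  general-population monthly row (December–March ≈ 34%), normalised;
- urban birth Bernoulli with a linear trend, default 0.35 → 0.55 across the
  birth-year range — a mid-range urbanisation level consistent with the
  period's census series, rising as the historical trend did;
- maternal age on an integer grid 15–60 with truncated-normal weights
  (mean 28, sd 6 years); paternal age = maternal + an integer offset
  (mean +5, sd 4 years), clipped to the same grid — jointly generated so
  the maternal-adjustment path is non-trivial;
- born abroad Bernoulli(0.081), the external migrant share;
- sibship size truncated-geometric on 1–12 with untruncated mean 3
  (achievers' families ran smaller than the general population's), and
  birth rank uniform within the sibship.

The returned reference tables are computed **exactly** from these
parameters (closed-form band sums, trend values at grid years, the implied
rank distribution Σ_{s≥r} p_s/s), never from the sample, so
generator/reference consistency is a testable property rather than an
assumption. Cases are selected among males with probability
logistic(c + Σ βₖ·exposureₖ); each βₖ is the log of a target odds ratio,
and c is calibrated by bisection to hit the expected sample size. In the
rare-outcome regime the selection OR equals the case-population OR up to
O(case fraction), which is what makes parameter recovery a meaningful
check. All draws flow from one `numpy.random.default_rng` (PCG64) stream
in a fixed order; selection uses a second stream seeded `seed + 1` so the
case draw is reproducible without regenerating the population.

What the generator does **not** emulate: non-response and directory-based
ascertainment, correlation between exposures beyond the parental-age
coupling (urbanicity and family size were historically linked), cohort
mortality, or any secular change in parental ages and sibship sizes.
Passing tests therefore show the estimator chain is correct and calibrated
under the stated structure — not that the historical estimates are free of
the biases those omitted features could induce.

## Study sizes and seeds

Parameter recovery uses 10 replicates of 200 000 individuals with ~2 000
cases (true ORs 2.0 first-born, 3.0 urban, 1.2 paternal age, 1.0
elsewhere); null calibration uses 200 replicates of 60 000 individuals with
~800 cases — large enough that every analysis cell exceeds ~50 and the Wald
interval operates in its nominal regime, while keeping a full run of either
study under half a minute on one CPU. Fixed seed sets make both studies
deterministic; the acceptance script derives its seeds from `--seed`.

## Known limitations

- The fixed-denominator convention understates uncertainty where a
  reference table is itself an estimate (notably the external migration
  share).
- The historical urbanicity denominator is internally inconsistent in the
  source tabulations (a stated 59.35% urban share vs the ~40.6% implied by
  the printed OR); the pipeline computes whatever the supplied reference
  implies and takes no side, so no numeric check is placed on that OR.
  Likewise the published seasonality OR (0.98) is not derivable from the
  printed aggregates (which imply ≈ 0.93) and is not targeted.
- Within-family birth-rank ORs are attenuated relative to the selection
  coefficient when sibship sizes vary (the comparison mixes sibships of
  different sizes); the estimate is reported against the uniform-within-
  sibship null as defined, not de-attenuated.
- Printed 2-decimal inputs limit reproduction of derived ratios to about
  ±0.01.
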