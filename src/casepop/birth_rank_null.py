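"""Reference distributions for the birth-rank analysis.

Two denominators are supported, mirroring the study's double comparison:

* the **general-population** rank distribution (from census tabulations of
  completed family sizes), loaded as a reference CSV; and
* the **within-family null** computed from the cases' own sibship sizes:
  under the null that within each sibship every sibling is equally likely to
  be the sampled case, P(rank = r) is the mean over families of 1/s for
  r <= s. Comparing cases against this null removes between-family
  confounding (family size, socio-economic level), at the price of needing
  each case's sibship size.

Ranks of 9 and above are pooled into a single "9 or more" bin, matching the
census tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .tables_io import PopulationReference, ReferenceKind

__all__ = ["RankDistribution", "within_family_null", "first_born_fraction", "from_reference"]

#: Top rank bin: rank R means "R or more".
POOL_RANK = 9


@dataclass(frozen=True)
class RankDistribution:
    """Probabilities over ranks 1..R; the last bin pools rank >= R."""

    probabilities: tuple[float, ...]
    source: Literal["general_population", "within_family"]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if np.any(p < 0):
            raise ValueError("negative rank probabilities")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError(f"rank probabilities sum to {p.sum()}, expected 1")
        if self.source == "within_family" and len(p) > 1:
            # uniform-within-sibship mixtures are non-increasing in rank
            # (the pooled top bin aggregates several ranks and is exempt)
            body = p[:-1]
            if np.any(np.diff(body) > 1e-12):
                raise ValueError("within-family null must be non-increasing in rank")

    def prob(self, rank: int) -> float:
        rank = min(rank, len(self.probabilities))
        return self.probabilities[rank - 1]


def within_family_null(
    sibship_sizes: Iterable[int], pool_rank: int = POOL_RANK
) -> RankDistribution:
    """Null rank distribution if each sibling were equally likely to be the case.

    P(rank = r) = mean over families of [1/s if r <= s else 0]; ranks
    >= ``pool_rank`` are pooled into the top bin.
    """
    sizes = np.asarray(list(sibship_sizes), dtype=int)
    if sizes.size == 0:
        raise ValueError("no sibship sizes supplied")
    if np.any(sizes < 1):
        raise ValueError("sibship sizes must be positive")
    max_rank = int(sizes.max())
    probs = np.zeros(max(max_rank, 1))
    for s in sizes:
        probs[:s] += 1.0 / s
    probs /= sizes.size
    if max_rank > pool_rank:
        pooled = np.concatenate([probs[: pool_rank - 1], [probs[pool_rank - 1 :].sum()]])
    else:
        pooled = probs
    pooled = pooled / pooled.sum()  # guard rounding at 1e-16 level
    return RankDistribution(probabilities=tuple(pooled), source="within_family")


def first_born_fraction(dist: RankDistribution) -> float:
    """P(rank = 1) under the reference distribution."""
    return dist.probabilities[0]


def from_reference(reference: PopulationReference) -> RankDistribution:
    """General-population rank distribution from a loaded reference table."""
    if reference.kind is not ReferenceKind.rank_distribution:
        raise ValueError(f"expected rank_distribution, got {reference.kind}")
    vec = np.asarray(reference.payload["ranks"], dtype=float)
    # printed tables carry 2-decimal rounding; renormalise to an exact
    # distribution (a <=0.01% rescale for such inputs)
    return RankDistribution(probabilities=tuple(vec / vec.sum()), source="general_population")
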