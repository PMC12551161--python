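"""Population-panel frequency filtering with coordinate liftover.

Candidates that survive segregation and impact filtering are repositioned
onto the population panel's assembly through a blockwise affine liftover
map and then screened against panel genotypes.  Two separately toggleable
exclusion rules are applied:

* ``af_above_threshold`` — panel allele frequency strictly above ``max_af``
  (default 5%): too common to cause a severe recessive disease.
* ``healthy_homozygotes_in_diverse_breeds`` — more than
  ``max_healthy_hom_alt`` homozygous-alternate panel animals (default 0)
  spread over at least ``min_breeds_for_diversity_exclusion`` breeds
  (default 2): healthy homozygotes in diverse breeds argue against
  causality even at low frequency.

Candidates that cannot be repositioned are retained but flagged rather
than silently dropped — a map gap makes them unassessable, not exonerated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consequence import IMPACT_RANK
from .model import (
    HET,
    HOM_ALT,
    MISSING,
    GenotypeMatrix,
    LiftoverMap,
    Variant,
)

EXCLUSION_REASONS = (
    "af_above_threshold",
    "healthy_homozygotes_in_diverse_breeds",
    "unmapped_policy",
)


@dataclass(frozen=True)
class PanelSummary:
    """Per-variant genotype summary over the population panel."""

    allele_frequency: float
    n_het: int
    n_hom_alt: int
    carrier_breeds: frozenset[str]
    n_called: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele_frequency outside [0, 1]")


@dataclass
class PopulationFilterPolicy:
    max_af: float = 0.05
    max_healthy_hom_alt: int = 0
    min_breeds_for_diversity_exclusion: int = 2
    exclude_unmapped: bool = False  # when True, unmapped candidates are excluded

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_af <= 1.0:
            raise ValueError("max_af outside [0, 1]")
        if self.max_healthy_hom_alt < 0 or self.min_breeds_for_diversity_exclusion < 1:
            raise ValueError("invalid policy thresholds")


def liftover_position(
    lmap: LiftoverMap, chrom: str, pos: int
) -> tuple[str, int] | None:
    """Affine strand-aware remapping of one position; None when unmapped."""
    return lmap.map_position(chrom, pos)


def panel_summary(
    matrix: GenotypeMatrix, breeds: dict[str, str], variant: Variant
) -> PanelSummary:
    """Allele frequency, het/hom-alt counts and carrier breeds for one variant.

    Counts are over non-missing calls only; carrier breeds are the breeds of
    samples carrying at least one alternate allele.
    """
    col = matrix.column(variant)  # raises KeyError when absent
    called = col != MISSING
    n_called = int(called.sum())
    n_het = int((col == HET).sum())
    n_hom = int((col == HOM_ALT).sum())
    af = (n_het + 2 * n_hom) / (2 * n_called) if n_called else 0.0
    carriers = frozenset(
        breeds.get(s, "unknown")
        for s, c in zip(matrix.sample_ids, col)
        if c in (HET, HOM_ALT)
    )
    return PanelSummary(af, n_het, n_hom, carriers, n_called)


def absent_summary(n_called: int) -> PanelSummary:
    """Summary for a candidate never observed in the panel (all reference)."""
    return PanelSummary(0.0, 0, 0, frozenset(), n_called)


@dataclass
class FilterCandidate:
    """One candidate entering the population filter."""

    variant: Variant
    impact: str = "HIGH"
    summary: PanelSummary | None = None  # None == unmapped / unassessable
    unmapped: bool = False


def _order_key(c: FilterCandidate):
    af = c.summary.allele_frequency if c.summary is not None else 0.0
    return (-IMPACT_RANK.get(c.impact, 0), af, c.variant.chrom, c.variant.pos)


def apply_population_filter(
    candidates: list[FilterCandidate],
    policy: PopulationFilterPolicy | None = None,
) -> tuple[list[FilterCandidate], list[tuple[FilterCandidate, str]]]:
    """Partition candidates into (retained, excluded-with-reason).

    Retained candidates are ordered deterministically: impact descending,
    panel allele frequency ascending, then chromosome and position.  The
    partition is exact: every input candidate lands in exactly one output.
    """
    policy = policy or PopulationFilterPolicy()
    retained: list[FilterCandidate] = []
    excluded: list[tuple[FilterCandidate, str]] = []
    for cand in candidates:
        if cand.summary is None or cand.unmapped:
            if policy.exclude_unmapped:
                excluded.append((cand, "unmapped_policy"))
            else:
                cand.unmapped = True
                retained.append(cand)
            continue
        s = cand.summary
        if s.allele_frequency > policy.max_af:
            excluded.append((cand, "af_above_threshold"))
        elif (
            s.n_hom_alt > policy.max_healthy_hom_alt
            and len(s.carrier_breeds) >= policy.min_breeds_for_diversity_exclusion
        ):
            excluded.append((cand, "healthy_homozygotes_in_diverse_breeds"))
        else:
            retained.append(cand)
    retained.sort(key=_order_key)
    return retained, excluded
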