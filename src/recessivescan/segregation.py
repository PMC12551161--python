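"""Recessive-model segregation filtering of cohort genotypes.

The default pattern keeps a variant only when every affected animal is
homozygous for the alternate allele and every control is homozygous
reference or heterozygous.  Uncertain-status animals never constrain.

Missing-genotype policy: a missing call in an affected sample fails the
variant (the required hom-alt state cannot be confirmed), while a missing
call in a control leaves it unconstrained (a violation cannot be
demonstrated).  The filter is conservative for cases and permissive for
controls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ZYGOSITY_CODES,
    GenotypeMatrix,
    SampleSheet,
    Variant,
)


@dataclass
class SegregationPattern:
    """Zygosity sets required/allowed per cohort role.

    The defaults encode a fully penetrant recessive model.  ``control_allowed``
    applies to non-missing control calls only; ``uncertain_constrained`` adds
    the control constraint to uncertain-status samples when True.
    """

    affected_required: frozenset[int] = frozenset({HOM_ALT})
    control_allowed: frozenset[int] = frozenset({HOM_REF, HET})
    uncertain_constrained: bool = False

    def __post_init__(self) -> None:
        if not self.affected_required:
            raise ValueError("affected_required must be non-empty")


def classify_zygosity(gt_text: str) -> str:
    """Classify a diploid GT string into hom_ref / het / hom_alt / missing."""
    sep = "|" if "|" in gt_text else "/"
    alleles = gt_text.split(sep)
    if len(alleles) != 2:
        raise ValueError(f"non-diploid genotype {gt_text!r}")
    if "." in alleles:
        return "missing"
    counts = sum(a != "0" for a in alleles)
    return {0: "hom_ref", 1: "het", 2: "hom_alt"}[counts]


def passes_segregation(
    calls: dict[str, list[int | str]], pattern: SegregationPattern | None = None
) -> bool:
    """Does one variant's per-role zygosity mapping satisfy the pattern?

    ``calls`` maps role -> list of zygosities (codes or names) for the
    samples with that role.
    """
    pattern = pattern or SegregationPattern()

    def codes(role: str) -> list[int]:
        return [ZYGOSITY_CODES.get(c, c) for c in calls.get(role, [])]

    for c in codes("affected"):
        if c == MISSING or c not in pattern.affected_required:
            return False
    constrained = ["control"] + (["uncertain"] if pattern.uncertain_constrained else [])
    for role in constrained:
        for c in codes(role):
            if c != MISSING and c not in pattern.control_allowed:
                return False
    return True


def segregation_filter(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    pattern: SegregationPattern | None = None,
) -> tuple[list[Variant], dict[str, int]]:
    """Vectorized recessive filter over the whole cohort matrix.

    Returns the order-preserving list of surviving variants and per-chromosome
    survivor counts.  Raises ``ValueError`` when the sheet names no affected
    samples.
    """
    pattern = pattern or SegregationPattern()
    affected = [matrix.sample_index(s) for s in sheet.affected_ids]
    if not affected:
        raise ValueError("no affected samples in the cohort sheet")
    controls = [matrix.sample_index(s) for s in sheet.control_ids]
    if pattern.uncertain_constrained:
        controls = controls + [matrix.sample_index(s) for s in sheet.uncertain_ids]

    calls = matrix.calls
    aff = calls[affected, :]
    ok = np.ones(matrix.n_variants, dtype=bool)
    aff_allowed = np.isin(aff, list(pattern.affected_required)) & (aff != MISSING)
    ok &= aff_allowed.all(axis=0)
    if controls:
        ctl = calls[controls, :]
        ctl_ok = np.isin(ctl, list(pattern.control_allowed)) | (ctl == MISSING)
        ok &= ctl_ok.all(axis=0)

    survivors = [v for v, keep in zip(matrix.variants, ok) if keep]
    per_chrom = Counter(v.chrom for v in survivors)
    return survivors, dict(per_chrom)
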