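"""Diagnostic genotype reporting and end-to-end pipeline orchestration.

The discovery cascade runs in fixed order:

1. recessive segregation filter over the cohort VCF,
2. consequence annotation against the gene model, keeping impacts at or
   above MODERATE,
3. liftover of the surviving candidates onto the panel assembly,
4. population-panel filtering (allele frequency, healthy homozygotes),
5. deterministic ranking (impact desc, panel AF asc, chrom/pos).

Stage counts are monotone non-increasing and echoed into a JSON-able
report together with every threshold and a provenance hash, so a run can
be audited and reproduced from the report alone.

The diagnostic-genotype utilities translate zygosity at the candidate
variant into test results (wildtype / carrier / affected genotype),
cross-tabulate them against histology review labels, and estimate the
population allele frequency with a Wilson score interval.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import io as rio
from .consequence import IMPACT_RANK, annotate
from .model import HET, HOM_ALT, HOM_REF, MISSING, ZYGOSITY_CODES
from .popfilter import (
    FilterCandidate,
    PopulationFilterPolicy,
    absent_summary,
    apply_population_filter,
    liftover_position,
    panel_summary,
)
from .segregation import SegregationPattern, segregation_filter

GENOTYPE_CLASSES = ("wildtype", "carrier", "affected_genotype", "no_call")

_CLASS_BY_CODE = {
    HOM_REF: "wildtype",
    HET: "carrier",
    HOM_ALT: "affected_genotype",
    MISSING: "no_call",
}


def classify_diagnostic_genotype(zygosity: int | str) -> str:
    """Map zygosity at the candidate variant to a diagnostic genotype class."""
    code = ZYGOSITY_CODES.get(zygosity, zygosity)
    try:
        return _CLASS_BY_CODE[code]
    except KeyError:
        raise ValueError(f"unknown zygosity {zygosity!r}") from None


def concordance_table(
    calls: dict[str, str], labels: dict[str, str]
) -> tuple[pd.DataFrame, float, list[str]]:
    """Cross-tabulate diagnostic genotype classes against histology labels.

    Concordance is the fraction of 'likely' histology labels whose genotype
    class is affected_genotype plus 'unlikely' labels whose class is not,
    over all likely+unlikely samples.  'equivocal' and 'none' labels are
    excluded from the denominator.  Returns (table, concordance, discordant
    sample ids).  Raises ``ValueError`` when no samples overlap.
    """
    shared = sorted(set(calls) & set(labels))
    if not shared:
        raise ValueError("no overlapping samples between calls and labels")
    table = pd.crosstab(
        pd.Series({s: calls[s] for s in shared}, name="genotype_class"),
        pd.Series({s: labels[s] for s in shared}, name="histology"),
    )
    num = 0
    den = 0
    discordant = []
    for s in shared:
        label = labels[s]
        if label not in ("likely", "unlikely"):
            continue
        den += 1
        hit = (
            calls[s] == "affected_genotype"
            if label == "likely"
            else calls[s] != "affected_genotype"
        )
        if hit:
            num += 1
        else:
            discordant.append(s)
    if den == 0:
        raise ValueError("no likely/unlikely samples to assess")
    return table, num / den, discordant


def estimate_allele_frequency(
    group_counts: list[tuple[int, int, int]], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Pooled allele frequency with a Wilson score interval.

    Each group is (n_het, n_hom_alt, n_samples); the pooled frequency is
    sum(het + 2*hom_alt) / sum(2*n_samples) and the interval is computed
    on the pooled allele counts.
    """
    alt = 0
    alleles = 0
    for n_het, n_hom, n in group_counts:
        if n <= 0:
            raise ValueError("group with zero samples")
        if n_het + n_hom > n:
            raise ValueError("carriers exceed group size")
        alt += n_het + 2 * n_hom
        alleles += 2 * n
    freq = alt / alleles
    lo, hi = proportion_confint(alt, alleles, alpha=alpha, method="wilson")
    return freq, (float(lo), float(hi))


@dataclass
class PipelineReport:
    """Cascade counts, ranked candidates, and provenance for one run."""

    stage_counts: dict[str, int]
    per_chromosome: dict[str, int]
    final_candidates: list[dict]
    excluded: list[dict]
    n_unmapped: int
    thresholds: dict
    provenance: dict
    top_is_unique: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage_counts": self.stage_counts,
                "per_chromosome": self.per_chromosome,
                "final_candidates": self.final_candidates,
                "excluded": self.excluded,
                "n_unmapped": self.n_unmapped,
                "thresholds": self.thresholds,
                "provenance": self.provenance,
                "top_is_unique": self.top_is_unique,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class PipelineInputs:
    cohort_vcf: str
    cohort_sheet: str
    gene_model: str
    reference: str
    panel_vcf: str
    panel_sheet: str
    liftover_map: str


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _cand_dict(c: FilterCandidate, call, lifted) -> dict:
    d = {
        "chrom": c.variant.chrom,
        "pos": c.variant.pos,
        "ref": c.variant.ref,
        "alt": c.variant.alt,
        "impact": c.impact,
        "consequence": call.consequence,
        "hgvs_c": call.hgvs_c,
        "hgvs_p": call.hgvs_p,
        "unmapped": c.unmapped,
    }
    if lifted is not None:
        d["lifted_chrom"], d["lifted_pos"] = lifted
    if c.summary is not None:
        d["panel_af"] = c.summary.allele_frequency
        d["panel_n_het"] = c.summary.n_het
        d["panel_n_hom_alt"] = c.summary.n_hom_alt
        d["panel_carrier_breeds"] = sorted(c.summary.carrier_breeds)
    return d


def run_pipeline(
    inputs: PipelineInputs,
    pattern: SegregationPattern | None = None,
    min_impact: str = "MODERATE",
    policy: PopulationFilterPolicy | None = None,
    seed: int | None = None,
) -> PipelineReport:
    """Run the full discovery cascade and return an auditable report.

    Any stage failure propagates as ``RuntimeError`` naming the stage.
    """
    pattern = pattern or SegregationPattern()
    policy = policy or PopulationFilterPolicy()
    min_rank = IMPACT_RANK[min_impact]

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    variants, matrix = stage("read_cohort", lambda: rio.read_vcf(inputs.cohort_vcf))
    sheet = stage("read_cohort", lambda: rio.read_sample_sheet(inputs.cohort_sheet))
    if not variants:
        raise RuntimeError("pipeline stage 'segregation' failed: empty cohort VCF")

    survivors, per_chrom = stage(
        "segregation", lambda: segregation_filter(matrix, sheet, pattern)
    )

    tx = stage(
        "annotation", lambda: rio.read_gene_model(inputs.gene_model, inputs.reference)
    )
    annotated = stage(
        "annotation", lambda: [(v, annotate(tx, v)) for v in survivors]
    )
    impactful = [
        (v, call) for v, call in annotated if IMPACT_RANK[call.impact] >= min_rank
    ]

    lmap = stage("liftover", lambda: rio.read_liftover_map(inputs.liftover_map))
    lifted = {
        v.key: liftover_position(lmap, v.chrom, v.pos) for v, _ in impactful
    }
    n_unmapped = sum(1 for m in lifted.values() if m is None)

    panel_variants, panel_matrix = stage(
        "population", lambda: rio.read_vcf(inputs.panel_vcf)
    )
    panel_sheet = stage(
        "population", lambda: rio.read_sample_sheet(inputs.panel_sheet)
    )
    panel_by_pos = {
        (v.chrom, v.pos, v.ref, v.alt): v for v in panel_variants
    }

    candidates = []
    calls_by_key = {}
    for v, call in impactful:
        calls_by_key[v.key] = call
        mapped = lifted[v.key]
        if mapped is None:
            candidates.append(FilterCandidate(v, call.impact, None, unmapped=True))
            continue
        tchrom, tpos = mapped
        pv = panel_by_pos.get((tchrom, tpos, v.ref, v.alt))
        if pv is None:
            summary = absent_summary(panel_matrix.n_samples)
        else:
            summary = panel_summary(panel_matrix, panel_sheet.breeds, pv)
        candidates.append(FilterCandidate(v, call.impact, summary))

    retained, excluded = stage(
        "population", lambda: apply_population_filter(candidates, policy)
    )
    n_af_excluded = sum(1 for _, r in excluded if r == "af_above_threshold")

    stage_counts = {
        "input": len(variants),
        "post_segregation": len(survivors),
        "post_impact": len(impactful),
        "post_liftover": len(impactful),  # unmapped candidates stay, flagged
        "post_population": len(impactful) - n_af_excluded,
    }
    final = [
        _cand_dict(c, calls_by_key[c.variant.key], lifted[c.variant.key])
        for c in retained
    ]
    excluded_out = [
        {**_cand_dict(c, calls_by_key[c.variant.key], lifted[c.variant.key]), "reason": r}
        for c, r in excluded
    ]
    thresholds = {
        "min_impact": min_impact,
        "max_af": policy.max_af,
        "max_healthy_hom_alt": policy.max_healthy_hom_alt,
        "min_breeds_for_diversity_exclusion": policy.min_breeds_for_diversity_exclusion,
        "affected_required": sorted(pattern.affected_required),
        "control_allowed": sorted(pattern.control_allowed),
        "uncertain_constrained": pattern.uncertain_constrained,
    }
    prov_payload = {
        "inputs": {
            k: _file_hash(getattr(inputs, k))
            for k in (
                "cohort_vcf",
                "cohort_sheet",
                "gene_model",
                "reference",
                "panel_vcf",
                "panel_sheet",
                "liftover_map",
            )
        },
        "thresholds": thresholds,
        "seed": seed,
    }
    provenance = {
        **prov_payload["inputs"],
        "seed": seed,
        "run_hash": hashlib.sha256(
            json.dumps(prov_payload, sort_keys=True).encode()
        ).hexdigest()[:12],
    }
    return PipelineReport(
        stage_counts=stage_counts,
        per_chromosome=per_chrom,
        final_candidates=final,
        excluded=excluded_out,
        n_unmapped=n_unmapped,
        thresholds=thresholds,
        provenance=provenance,
        top_is_unique=len(final) >= 1
        and (len(final) == 1 or final[0]["impact"] != final[1]["impact"]),
    )


def write_report(report: PipelineReport, json_path: str, tsv_path: str | None = None) -> None:
    with open(json_path, "w") as fh:
        fh.write(report.to_json() + "\n")
    if tsv_path:
        rows = [{"rank": i + 1, **c} for i, c in enumerate(report.final_candidates)]
        rows += [{"rank": "", **c} for c in report.excluded]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
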