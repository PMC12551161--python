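"""Deterministic synthetic study generator.

Builds, from a single seed, every input the discovery pipeline consumes:

* a random multi-chromosome reference FASTA carrying one multi-exon
  ALS2-like gene model (GFF3) whose coding sequence is constructed
  *backwards* from the protein the analysis must recover,
* an 8-animal WGS-style cohort VCF (5 affected / 2 control / 1 uncertain)
  with one planted causal 2 bp frameshift deletion, one planted decoy
  missense (healthy homozygotes in several panel breeds), one planted
  common missense (high panel frequency), and neutral background variants
  in Hardy-Weinberg proportions,
* a 935-sample / 70-breed population-panel VCF on a *second* coordinate
  system reached through a blockwise liftover map,
* a 10-case / 98-control SNP-array cohort in which 9 of the 10 cases share
  one long autozygous haplotype block containing the gene,
* sample sheets, a liftover block map, and a JSON truth record naming the
  planted variants and the autozygous interval.

The CDS is constructed so that deleting the two bases at the configured
CDS position yields exactly the worked frameshift example: the mutated
codon switches leucine to glycine, 16 novel residues follow, and the
premature stop lands at new-frame position 17 — replacing the C-terminal
residues of the wildtype protein from that codon onwards.

All randomness flows through one seeded :class:`numpy.random.Generator`
hierarchy; re-running with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import io as rio
from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    GenotypeMatrix,
    LiftoverBlock,
    LiftoverMap,
    SampleSheet,
    TranscriptModel,
    Variant,
    revcomp,
)

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

# gene layout constants (bp)
_UTR5 = 100
_UTR3 = 200
_INTRON = 2_000
_EARLY_CDS = 150
_N_EARLY_EXONS = 25
_N_EXONS = 26

# fixed codons supporting the planted missense variants
_COMMON_CODON_IDX = 72   # codon set to Asn; c.215 A>G makes it Ser
_DECOY_CODON_IDX = 100   # codon set to Asp; c.298 G>C makes it His


@dataclass
class GeneratorConfig:
    """Study-shaped generator configuration; the defaults are the study conditions."""

    seed: int = 0
    n_affected: int = 5
    n_controls: int = 2
    n_uncertain: int = 1
    panel_size: int = 935
    n_breeds: int = 70
    merino_panel_count: int = 128
    array_cases: int = 10
    array_controls: int = 98
    n_background_variants: int = 2000
    n_panel_background_variants: int = 200
    n_array_snps: int = 5000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 12_000_000, "chr3": 6_000_000}
    )
    causal_cds_del_start: int = 4138
    protein_length: int = 1666
    gene_chrom: str = "chr2"
    gene_start: int = 9_000_000
    gene_strand: str = "+"
    block_width: int = 4_500_000  # autozygous block width on the array
    array_missing_rate: float = 0.01

    def validate(self) -> None:
        counts = [
            self.n_affected,
            self.n_controls,
            self.panel_size,
            self.n_breeds,
            self.array_cases,
            self.array_controls,
            self.n_background_variants,
            self.n_array_snps,
            self.protein_length,
        ]
        if any(c <= 0 for c in counts) or self.n_uncertain < 0:
            raise ValueError("all counts must be positive")
        ds = self.causal_cds_del_start
        if ds + 1 > 3 * self.protein_length:
            raise ValueError("causal deletion outside the CDS")
        if (ds - 1) % 3 != 0:
            raise ValueError("causal_cds_del_start must be the first base of a codon")
        c0 = (ds - 1) // 3 + 1
        if c0 <= _DECOY_CODON_IDX + 1:
            raise ValueError("causal codon must lie beyond the planted missense codons")
        if c0 + 17 > self.protein_length:
            raise ValueError("too little CDS downstream of the deletion for the fs*17 stop")
        if 3 * (self.protein_length + 1) <= _N_EARLY_EXONS * _EARLY_CDS:
            raise ValueError("protein too short for the 26-exon layout")
        if self.gene_strand not in "+-":
            raise ValueError("gene_strand must be '+' or '-'")
        if self.gene_chrom not in self.chrom_lengths:
            raise ValueError(f"gene_chrom {self.gene_chrom} not in chrom_lengths")
        if self.merino_panel_count < 2 or self.panel_size - self.merino_panel_count < 10:
            raise ValueError("panel too small to satisfy carrier/decoy constraints")
        if self.n_breeds < 3:
            raise ValueError("need at least 3 breeds")

    @property
    def causal_codon(self) -> int:
        return (self.causal_cds_del_start - 1) // 3 + 1

    @property
    def cds_length(self) -> int:
        return 3 * (self.protein_length + 1)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class SyntheticDataset:
    """Paths of everything the generator wrote, plus the truth record."""

    outdir: str
    reference: str
    gene_model: str
    cohort_vcf: str
    cohort_sheet: str
    panel_vcf: str
    panel_sheet: str
    array_genotypes: str
    array_snp_map: str
    array_sheet: str
    liftover_map: str
    truth_path: str
    truth: dict


# ---------------------------------------------------------------------------
# CDS construction
# ---------------------------------------------------------------------------

def _pick(rng: np.random.Generator, options: list[str]) -> str:
    return options[int(rng.integers(len(options)))]


def _build_cds(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """Coding sequence (incl. terminal stop) engineered around the planted variants.

    Codon ``c0`` (the causal codon) is leucine CTG; the -2 frameshifted
    read-through from ``c0`` encodes glycine, then 15 further sense codons,
    then a stop, guaranteeing ``fs*17`` for the 2 bp deletion.
    """
    c0 = cfg.causal_codon
    codons: list[str] = [""] * (cfg.protein_length + 1)  # 1-based

    sense = list(SENSE_CODONS)
    for i in range(1, cfg.protein_length + 1):
        codons[i] = _pick(rng, sense)
    codons[_COMMON_CODON_IDX] = "AAT"  # Asn
    codons[_DECOY_CODON_IDX] = "GAT"   # Asp

    # keep the VCF record for the CT deletion left-aligned: previous codon
    # must not end in T (which would allow a leftward shift of the CT run)
    while codons[c0 - 1][2] == "T":
        codons[c0 - 1] = _pick(rng, sense)
    codons[c0] = "CTG"  # Leu; 3rd base G seeds the frameshifted glycine

    # shifted codon k reads (3rd base of codon c0+k-1, first two of codon c0+k)
    for k in range(1, 17):
        prev3 = codons[c0 + k - 1][2]
        if k == 1:
            choices = [c for c in sense if c[0] == "G"]  # shifted codon = G G ? = Gly
        elif k == 16:
            choices = [
                c for c in sense if (prev3 + c[:2]) not in _STOPS and c[2] == "T"
            ]
        else:
            choices = [c for c in sense if (prev3 + c[:2]) not in _STOPS]
        codons[c0 + k] = _pick(rng, choices)
    prev3 = codons[c0 + 16][2]  # == 'T'
    choices = [c for c in sense if (prev3 + c[:2]) in _STOPS]
    codons[c0 + 17] = _pick(rng, choices)

    return "".join(codons[1:]) + "TAA"


# ---------------------------------------------------------------------------
# Gene layout and reference
# ---------------------------------------------------------------------------

def _layout_gene(cfg: GeneratorConfig, cds_seq: str) -> TranscriptModel:
    last_cds = cfg.cds_length - _N_EARLY_EXONS * _EARLY_CDS
    g0 = cfg.gene_start
    exons: list[tuple[int, int]] = []
    if cfg.gene_strand == "+":
        start = g0
        exons.append((start, start + _UTR5 + _EARLY_CDS - 1))
        cds_start = start + _UTR5
        for _ in range(_N_EARLY_EXONS - 1):
            start = exons[-1][1] + _INTRON + 1
            exons.append((start, start + _EARLY_CDS - 1))
        start = exons[-1][1] + _INTRON + 1
        exons.append((start, start + last_cds + _UTR3 - 1))
        cds_end = start + last_cds - 1
    else:
        start = g0
        exons.append((start, start + _UTR3 + last_cds - 1))
        cds_start = start + _UTR3
        for _ in range(_N_EARLY_EXONS - 1):
            start = exons[-1][1] + _INTRON + 1
            exons.append((start, start + _EARLY_CDS - 1))
        start = exons[-1][1] + _INTRON + 1
        exons.append((start, start + _EARLY_CDS + _UTR5 - 1))
        cds_end = start + _EARLY_CDS - 1
    if exons[-1][1] > cfg.chrom_lengths[cfg.gene_chrom]:
        raise ValueError("gene does not fit on its chromosome")
    return TranscriptModel(
        chrom=cfg.gene_chrom,
        strand=cfg.gene_strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        cds_seq=cds_seq,
        gene_id="ALS2LIKE",
        transcript_id="ALS2LIKE.t1",
    )


_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_chromosome(rng: np.random.Generator, length: int) -> bytearray:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return bytearray(_LUT[codes].tobytes())


def _build_reference(
    rng: np.random.Generator, cfg: GeneratorConfig, tx: TranscriptModel
) -> dict[str, bytearray]:
    ref = {c: _random_chromosome(rng, l) for c, l in cfg.chrom_lengths.items()}
    genomic_cds = tx.cds_seq if tx.strand == "+" else revcomp(tx.cds_seq)
    chrom = ref[tx.chrom]
    offset = 0
    for a, b in tx.cds_intervals:
        n = b - a + 1
        chrom[a - 1 : b] = genomic_cds[offset : offset + n].encode()
        offset += n
    return ref


def _base_at(ref: dict[str, bytearray], chrom: str, pos: int) -> str:
    return chr(ref[chrom][pos - 1])


# ---------------------------------------------------------------------------
# Planted variant records
# ---------------------------------------------------------------------------

def _planted_variants(
    cfg: GeneratorConfig, tx: TranscriptModel, ref: dict[str, bytearray]
) -> dict[str, Variant]:
    ds = cfg.causal_cds_del_start
    g1, g2 = tx.cds_to_genomic(ds), tx.cds_to_genomic(ds + 1)
    lo, hi = min(g1, g2), max(g1, g2)
    anchor = lo - 1
    ref_allele = "".join(_base_at(ref, tx.chrom, p) for p in range(anchor, hi + 1))
    causal = Variant(tx.chrom, anchor, ref_allele, ref_allele[0], id="causal")

    def snv(cpos: int, alt_coding: str, vid: str) -> Variant:
        g = tx.cds_to_genomic(cpos)
        ref_base = _base_at(ref, tx.chrom, g)
        alt = alt_coding if tx.strand == "+" else alt_coding.translate(
            str.maketrans("ACGT", "TGCA")
        )
        return Variant(tx.chrom, g, ref_base, alt, id=vid)

    decoy = snv((_DECOY_CODON_IDX - 1) * 3 + 1, "C", "decoy")      # c.298G>C Asp100His
    common = snv((_COMMON_CODON_IDX - 1) * 3 + 2, "G", "common")   # c.215A>G Asn72Ser
    return {"causal": causal, "decoy": decoy, "common": common}


# ---------------------------------------------------------------------------
# Genotype planting (public operations)
# ---------------------------------------------------------------------------

def plant_cohort_genotypes(
    variants: list[Variant],
    roles: dict[str, str],
    seed: int,
    segregating: tuple = (),
) -> GenotypeMatrix:
    """Cohort genotype matrix with planted segregation patterns.

    Background variants draw a per-variant alternate allele frequency
    uniformly on [0.05, 0.5] and genotypes in Hardy-Weinberg proportions.
    Variants listed in ``segregating`` (keys or Variants) instead get the
    recessive pattern: affecteds hom-alt, controls alternating het /
    hom-ref, uncertain-status samples random.
    """
    if not variants:
        raise ValueError("empty variant list")
    if "affected" not in roles.values():
        raise ValueError("roles must include at least one affected sample")
    rng = np.random.default_rng(seed)
    sample_ids = list(roles)
    n_s, n_v = len(sample_ids), len(variants)
    freqs = rng.uniform(0.05, 0.5, size=n_v)
    calls = rng.binomial(2, freqs[None, :], size=(n_s, n_v)).astype(np.int8)
    seg_keys = {v.key if isinstance(v, Variant) else tuple(v) for v in segregating}
    for j, v in enumerate(variants):
        if v.key not in seg_keys:
            continue
        toggle = 0
        for i, s in enumerate(sample_ids):
            role = roles[s]
            if role == "affected":
                calls[i, j] = HOM_ALT
            elif role == "control":
                calls[i, j] = HET if toggle % 2 == 0 else HOM_REF
                toggle += 1
            else:
                calls[i, j] = int(rng.integers(0, 3))
    return GenotypeMatrix(sample_ids, variants, calls)


def plant_panel_genotypes(
    variants: list[Variant],
    panel_spec: dict[str, int],
    seed: int,
    special: dict[tuple, str] | None = None,
) -> GenotypeMatrix:
    """Population-panel genotype matrix with planted carrier structure.

    ``panel_spec`` maps breed -> sample count.  ``special`` maps variant
    keys to one of:

    * ``"causal"`` — exactly 2 heterozygous Merino carriers, 0 hom-alt;
    * ``"decoy"`` — exactly 10 hom-alt animals spread over 4 non-Merino
      breeds (allele frequency well under 5%);
    * ``"common"`` — Hardy-Weinberg at allele frequency 0.3 (above the 5%
      filter threshold).

    Remaining variants are background with per-variant frequency uniform
    on [0.005, 0.4]; at least one background variant is guaranteed to have
    a realized frequency above 5%.
    """
    special = special or {}
    panel_size = sum(panel_spec.values())
    if panel_size < 2:
        raise ValueError("panel too small to satisfy constraints")
    if special:
        if panel_spec.get("Merino", 0) < 2:
            raise ValueError("panel too small: need >= 2 Merino samples for carriers")
        if panel_size - panel_spec.get("Merino", 0) < 10:
            raise ValueError("panel too small: need >= 10 non-Merino samples for decoy")
    if not variants:
        raise ValueError("empty variant list")

    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    breeds: list[str] = []
    for breed, count in panel_spec.items():
        for _ in range(count):
            sample_ids.append(f"P{len(sample_ids) + 1:04d}")
            breeds.append(breed)
    breeds_arr = np.array(breeds)
    n_s, n_v = len(sample_ids), len(variants)

    freqs = rng.uniform(0.005, 0.4, size=n_v)
    calls = rng.binomial(2, freqs[None, :], size=(n_s, n_v)).astype(np.int8)

    merino_idx = np.flatnonzero(breeds_arr == "Merino")
    other_breeds = sorted(set(panel_spec) - {"Merino"})
    background_cols = []
    for j, v in enumerate(variants):
        kind = special.get(v.key)
        if kind is None:
            background_cols.append(j)
            continue
        if kind == "causal":
            calls[:, j] = HOM_REF
            carriers = rng.choice(merino_idx, size=2, replace=False)
            calls[carriers, j] = HET
        elif kind == "decoy":
            calls[:, j] = HOM_REF
            chosen_breeds = [
                other_breeds[int(k)]
                for k in rng.choice(len(other_breeds), size=4, replace=False)
            ]
            per_breed = [3, 3, 2, 2]
            for breed, count in zip(chosen_breeds, per_breed):
                idx = np.flatnonzero(breeds_arr == breed)
                chosen = rng.choice(idx, size=count, replace=False)
                calls[chosen, j] = HOM_ALT
        elif kind == "common":
            col = rng.binomial(2, 0.3, size=n_s).astype(np.int8)
            if col.sum() <= 0.05 * 2 * n_s:  # guarantee AF > 5% for every seed
                col[: int(0.2 * n_s)] = HET
            calls[:, j] = col
        else:
            raise ValueError(f"unknown special kind {kind!r}")

    if background_cols:
        sums = calls[:, background_cols].sum(axis=0)
        if not np.any(sums > 0.05 * 2 * n_s):
            j = background_cols[0]
            calls[: max(1, n_s // 5), j] = HET

    return GenotypeMatrix(sample_ids, variants, calls)


# ---------------------------------------------------------------------------
# Liftover map
# ---------------------------------------------------------------------------

_BLOCK_GAP = 25_000


def _build_liftover(cfg: GeneratorConfig) -> LiftoverMap:
    """Three blocks per chromosome, fixed offsets, one minus-strand block."""
    blocks: list[LiftoverBlock] = []
    for ci, (chrom, length) in enumerate(cfg.chrom_lengths.items()):
        cut1, cut2 = length // 3, 2 * length // 3
        spans = [
            (1, cut1 - _BLOCK_GAP),
            (cut1 + _BLOCK_GAP, cut2 - _BLOCK_GAP),
            (cut2 + _BLOCK_GAP, length),
        ]
        for bi, (a, b) in enumerate(spans):
            strand = "-" if (ci == 2 and bi == 1) else "+"
            offset = 100_000 * (bi + 1) + 137 * (ci + 1)
            if strand == "+":
                tgt_start = a + offset
            else:
                tgt_start = a + offset  # reflected within [tgt_start, tgt_start+len)
            blocks.append(
                LiftoverBlock(chrom, a, b, f"{chrom}_alt", tgt_start, strand)
            )
    return LiftoverMap(blocks)


# ---------------------------------------------------------------------------
# Array cohort
# ---------------------------------------------------------------------------

def _array_snp_map(cfg: GeneratorConfig) -> tuple[list[str], list[str], np.ndarray]:
    total = sum(cfg.chrom_lengths.values())
    ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    remaining = cfg.n_array_snps
    items = list(cfg.chrom_lengths.items())
    for k, (chrom, length) in enumerate(items):
        count = (
            remaining
            if k == len(items) - 1
            else int(round(cfg.n_array_snps * length / total))
        )
        remaining -= count
        spacing = length // (count + 1)
        for j in range(count):
            ids.append(f"SNP{len(ids) + 1:06d}")
            chroms.append(chrom)
            positions.append(spacing * (j + 1))
    return ids, chroms, np.array(positions)


def _build_array(
    rng: np.random.Generator, cfg: GeneratorConfig, block: tuple[str, int, int]
):
    import pandas as pd

    ids, chroms, positions = _array_snp_map(cfg)
    n_snps = len(ids)
    case_ids = [f"CASE{i + 1:02d}" for i in range(cfg.array_cases)]
    control_ids = [f"ACTRL{i + 1:03d}" for i in range(cfg.array_controls)]
    samples = case_ids + control_ids
    n_s = len(samples)

    freqs = rng.uniform(0.1, 0.45, size=n_snps)
    geno = rng.binomial(2, freqs[None, :], size=(n_s, n_snps)).astype(float)

    bchrom, bstart, bend = block
    in_block = np.array(
        [c == bchrom and bstart <= p <= bend for c, p in zip(chroms, positions)]
    )
    hap = rng.integers(0, 2, size=int(in_block.sum()))  # shared haplotype allele
    sharing = cfg.array_cases - 1  # 9 of the 10 cases share the block
    for i in range(sharing):
        geno[i, in_block] = 2.0 * hap

    missing = rng.random((n_s, n_snps)) < cfg.array_missing_rate
    geno[missing] = np.nan

    genotypes = pd.DataFrame(geno, index=samples, columns=ids)
    snp_map = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": positions})
    sheet = SampleSheet(
        sample_ids=samples,
        roles={s: ("case" if s in case_ids else "array_control") for s in samples},
        breeds={s: "Merino" for s in samples},
        histology={s: ("likely" if s in case_ids else "none") for s in samples},
    )
    return genotypes, snp_map, sheet, case_ids[:sharing]


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def generate_dataset(cfg: GeneratorConfig, outdir: str) -> SyntheticDataset:
    """Write the complete synthetic study into ``outdir`` and return its paths.

    Re-running with an identical configuration reproduces every output file
    byte for byte.
    """
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    tag = f"seed={cfg.seed} config={cfg.config_hash()}"

    ss = np.random.SeedSequence(cfg.seed)
    sub = ss.generate_state(8) % (2**31)
    rng_cds = np.random.default_rng(int(sub[0]))
    rng_ref = np.random.default_rng(int(sub[1]))
    rng_bg = np.random.default_rng(int(sub[2]))
    seed_cohort = int(sub[3])
    seed_panel = int(sub[4])
    rng_array = np.random.default_rng(int(sub[5]))
    rng_panel_bg = np.random.default_rng(int(sub[6]))

    # gene, reference, planted variants
    cds = _build_cds(rng_cds, cfg)
    tx = _layout_gene(cfg, cds)
    ref = _build_reference(rng_ref, cfg, tx)
    planted = _planted_variants(cfg, tx, ref)

    lmap = _build_liftover(cfg)
    gene_lo, gene_hi = tx.span
    for pos in (gene_lo, gene_hi):
        if lmap.map_position(tx.chrom, pos) is None:
            raise ValueError("gene span crosses a liftover block gap; move gene_start")

    # autozygous block: distal end of the gene chromosome, containing the gene
    chrom_len = cfg.chrom_lengths[cfg.gene_chrom]
    block_end = chrom_len - 1_000_000
    block_start = block_end - cfg.block_width
    if not (block_start <= gene_lo and gene_hi <= block_end):
        raise ValueError("gene does not lie inside the autozygous block")
    block = (cfg.gene_chrom, block_start, block_end)

    chrom_order = {c: i for i, c in enumerate(cfg.chrom_lengths)}

    # --- cohort ------------------------------------------------------------
    margin = 5_000
    taken: set[tuple[str, int]] = set()
    bg_variants: list[Variant] = []
    chrom_names = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    while len(bg_variants) < cfg.n_background_variants:
        c = chrom_names[int(rng_bg.choice(len(chrom_names), p=weights))]
        pos = int(rng_bg.integers(1, cfg.chrom_lengths[c] + 1))
        if c == tx.chrom and gene_lo - margin <= pos <= gene_hi + margin:
            continue
        if (c, pos) in taken:
            continue
        taken.add((c, pos))
        ref_base = _base_at(ref, c, pos)
        alt = _pick(rng_bg, [b for b in _BASES if b != ref_base])
        bg_variants.append(Variant(c, pos, ref_base, alt))

    cohort_variants = sorted(
        bg_variants + list(planted.values()),
        key=lambda v: (chrom_order[v.chrom], v.pos, v.ref, v.alt),
    )
    roles: dict[str, str] = {}
    histology: dict[str, str] = {}
    for i in range(cfg.n_affected):
        roles[f"AFF{i + 1}"] = "affected"
        histology[f"AFF{i + 1}"] = "likely"
    for i in range(cfg.n_controls):
        roles[f"CTRL{i + 1}"] = "control"
        histology[f"CTRL{i + 1}"] = "unlikely"
    for i in range(cfg.n_uncertain):
        roles[f"UNC{i + 1}"] = "uncertain"
        histology[f"UNC{i + 1}"] = "equivocal"
    cohort_matrix = plant_cohort_genotypes(
        cohort_variants,
        roles,
        seed_cohort,
        segregating=tuple(planted.values()),
    )
    cohort_sheet = SampleSheet(
        sample_ids=list(roles),
        roles=roles,
        breeds={s: "Merino" for s in roles},
        histology=histology,
    )

    # --- panel (target assembly coordinates) -------------------------------
    def lift_variant(v: Variant) -> Variant:
        mapped = lmap.map_position(v.chrom, v.pos)
        if mapped is None:
            raise ValueError(f"planted variant {v.key} unmapped")
        tchrom, tpos = mapped
        return Variant(tchrom, tpos, v.ref, v.alt, id=v.id)

    panel_planted = {name: lift_variant(v) for name, v in planted.items()}
    panel_taken = {(v.chrom, v.pos) for v in panel_planted.values()}
    panel_bg: list[Variant] = []
    while len(panel_bg) < cfg.n_panel_background_variants:
        c = chrom_names[int(rng_panel_bg.choice(len(chrom_names), p=weights))]
        pos = int(rng_panel_bg.integers(1, cfg.chrom_lengths[c] + 1))
        mapped = lmap.map_position(c, pos)
        if mapped is None:
            continue
        tchrom, tpos = mapped
        if (tchrom, tpos) in panel_taken:
            continue
        panel_taken.add((tchrom, tpos))
        ref_base = _base_at(ref, c, pos)
        alt = _pick(rng_panel_bg, [b for b in _BASES if b != ref_base])
        panel_bg.append(Variant(tchrom, tpos, ref_base, alt))

    tgt_order = {f"{c}_alt": i for i, c in enumerate(cfg.chrom_lengths)}
    panel_variants = sorted(
        panel_bg + list(panel_planted.values()),
        key=lambda v: (tgt_order[v.chrom], v.pos, v.ref, v.alt),
    )
    breeds_spec: dict[str, int] = {"Merino": cfg.merino_panel_count}
    rest = cfg.panel_size - cfg.merino_panel_count
    n_other = cfg.n_breeds - 1
    base_count, extra = divmod(rest, n_other)
    for i in range(n_other):
        breeds_spec[f"Breed{i + 1:02d}"] = base_count + (1 if i < extra else 0)
    panel_matrix = plant_panel_genotypes(
        panel_variants,
        breeds_spec,
        seed_panel,
        special={
            panel_planted["causal"].key: "causal",
            panel_planted["decoy"].key: "decoy",
            panel_planted["common"].key: "common",
        },
    )
    panel_breed_by_sample = {}
    i = 0
    for breed, count in breeds_spec.items():
        for _ in range(count):
            panel_breed_by_sample[panel_matrix.sample_ids[i]] = breed
            i += 1
    panel_sheet = SampleSheet(
        sample_ids=panel_matrix.sample_ids,
        roles={s: "panel" for s in panel_matrix.sample_ids},
        breeds=panel_breed_by_sample,
        histology={s: "none" for s in panel_matrix.sample_ids},
    )

    # --- array cohort -------------------------------------------------------
    array_geno, snp_map, array_sheet, sharing_cases = _build_array(rng_array, cfg, block)

    # --- write everything ---------------------------------------------------
    paths = SyntheticDataset(
        outdir=outdir,
        reference=os.path.join(outdir, "reference.fa"),
        gene_model=os.path.join(outdir, "gene_model.gff3"),
        cohort_vcf=os.path.join(outdir, "cohort.vcf"),
        cohort_sheet=os.path.join(outdir, "cohort_samples.tsv"),
        panel_vcf=os.path.join(outdir, "panel.vcf"),
        panel_sheet=os.path.join(outdir, "panel_samples.tsv"),
        array_genotypes=os.path.join(outdir, "array_genotypes.tsv"),
        array_snp_map=os.path.join(outdir, "array_snps.tsv"),
        array_sheet=os.path.join(outdir, "array_samples.tsv"),
        liftover_map=os.path.join(outdir, "liftover.tsv"),
        truth_path=os.path.join(outdir, "truth.json"),
        truth={},
    )
    rio.write_fasta({c: bytes(s).decode() for c, s in ref.items()}, paths.reference)
    rio.write_gene_model(tx, paths.gene_model, source=tag)
    rio.write_vcf(cohort_variants, cohort_matrix, paths.cohort_vcf, source=tag)
    rio.write_sample_sheet(cohort_sheet, paths.cohort_sheet, source=tag)
    rio.write_vcf(panel_variants, panel_matrix, paths.panel_vcf, source=tag)
    rio.write_sample_sheet(panel_sheet, paths.panel_sheet, source=tag)
    rio.write_array_genotypes(array_geno, paths.array_genotypes, source=tag)
    rio.write_snp_map(snp_map, paths.array_snp_map, source=tag)
    rio.write_sample_sheet(array_sheet, paths.array_sheet, source=tag)
    rio.write_liftover_map(lmap, paths.liftover_map, source=tag)

    def vdict(v: Variant) -> dict:
        return {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}

    truth = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "causal": {
            **vdict(planted["causal"]),
            "cds_del_start": cfg.causal_cds_del_start,
            "panel": vdict(panel_planted["causal"]),
        },
        "decoy": {**vdict(planted["decoy"]), "panel": vdict(panel_planted["decoy"])},
        "common_missense": {
            **vdict(planted["common"]),
            "panel": vdict(panel_planted["common"]),
        },
        "autozygous_block": {"chrom": block[0], "start": block[1], "end": block[2]},
        "sharing_cases": sharing_cases,
        "gene": {
            "chrom": tx.chrom,
            "strand": tx.strand,
            "span": list(tx.span),
            "n_exons": len(tx.exons),
        },
    }
    with open(paths.truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths.truth = truth
    return paths
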