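"""Core data model shared by every stage of the pipeline.

The pipeline moves genotype data through four containers:

* :class:`Variant` — one normalized biallelic genomic change,
* :class:`GenotypeMatrix` — samples x variants zygosity calls,
* :class:`TranscriptModel` — a stranded multi-exon gene model with CDS,
* :class:`LiftoverMap` — blockwise affine coordinate remapping between
  two assemblies.

Coordinates are 1-based inclusive everywhere in this module, matching the
VCF/GFF3 convention of the files they are read from.  Readers and writers
(:mod:`recessivescan.io`) are the only place where any conversion happens.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

# Zygosity codes used in GenotypeMatrix.calls (int8).
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

ZYGOSITY_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}
ZYGOSITY_CODES = {v: k for k, v in ZYGOSITY_NAMES.items()}

SAMPLE_ROLES = frozenset(
    {"affected", "control", "uncertain", "panel", "case", "array_control"}
)
HISTOLOGY_LABELS = frozenset({"likely", "unlikely", "equivocal", "none"})

_DNA = frozenset("ACGT")

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Variant:
    """One normalized biallelic variant (VCF-style, anchor base included for indels)."""

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _DNA:
                raise ValueError(f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref) == 1

    def deleted_span(self) -> tuple[int, int] | None:
        """Genomic interval (1-based inclusive) of bases removed by a deletion.

        With the VCF anchor-base convention REF=XYZ/ALT=X the removed bases
        are pos+1 .. pos+len(REF)-1.  Returns None for non-deletions.
        """
        if not self.is_deletion:
            return None
        return (self.pos + 1, self.pos + len(self.ref) - 1)


class GenotypeMatrix:
    """Zygosity calls for samples x variants.

    ``calls`` is an int8 array of shape (n_samples, n_variants) holding the
    codes HOM_REF / HET / HOM_ALT / MISSING.
    """

    def __init__(self, sample_ids: list[str], variants: list[Variant], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(sample_ids), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {-1,0,1,2}")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        self.sample_ids = list(sample_ids)
        self.variants = list(variants)
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._variant_index = {v.key: j for j, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def variant_index(self, variant: Variant) -> int:
        try:
            return self._variant_index[variant.key]
        except KeyError:
            raise KeyError(f"variant {variant.key} not in matrix") from None

    def column(self, variant: Variant) -> np.ndarray:
        """Calls for one variant across all samples."""
        return self.calls[:, self.variant_index(variant)]

    def call(self, sample_id: str, variant: Variant) -> int:
        return int(self.calls[self.sample_index(sample_id), self.variant_index(variant)])

    def subset_variants(self, keep: list[Variant]) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in keep]
        return GenotypeMatrix(self.sample_ids, keep, self.calls[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class SampleSheet:
    """Per-sample metadata: role in the study, breed, histology review label."""

    sample_ids: list[str]
    roles: dict[str, str]
    breeds: dict[str, str]
    histology: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in sheet")
        for s in self.sample_ids:
            role = self.roles.get(s)
            if role not in SAMPLE_ROLES:
                raise ValueError(f"unknown role {role!r} for sample {s}")
            label = self.histology.get(s, "none")
            if label not in HISTOLOGY_LABELS:
                raise ValueError(f"unknown histology label {label!r} for sample {s}")

    def ids_with_role(self, role: str) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] == role]

    @property
    def affected_ids(self) -> list[str]:
        return self.ids_with_role("affected")

    @property
    def control_ids(self) -> list[str]:
        return self.ids_with_role("control")

    @property
    def uncertain_ids(self) -> list[str]:
        return self.ids_with_role("uncertain")


class TranscriptModel:
    """A single stranded multi-exon transcript with an attached spliced CDS.

    ``exons`` are 1-based inclusive genomic intervals sorted by genomic
    position; ``cds_start``/``cds_end`` bound the coding region in genomic
    coordinates (strand-independent, cds_start <= cds_end).  ``cds_seq`` is
    the spliced coding sequence in transcription order (reverse-complemented
    for minus-strand models) and includes the terminal stop codon.
    """

    def __init__(
        self,
        chrom: str,
        strand: str,
        exons: list[tuple[int, int]],
        cds_start: int,
        cds_end: int,
        cds_seq: str,
        gene_id: str = "gene1",
        transcript_id: str = "tx1",
    ):
        if strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        exons = sorted((int(a), int(b)) for a, b in exons)
        for (a, b) in exons:
            if a > b:
                raise ValueError(f"exon start {a} > end {b}")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 <= b1:
                raise ValueError("exons overlap or touch")
        if cds_start > cds_end:
            raise ValueError("cds_start > cds_end")
        self.chrom = chrom
        self.strand = strand
        self.exons = exons
        self.cds_start = int(cds_start)
        self.cds_end = int(cds_end)
        self.cds_seq = cds_seq.upper()
        self.gene_id = gene_id
        self.transcript_id = transcript_id
        self._cds_ivals = self._compute_cds_intervals()
        n = sum(b - a + 1 for a, b in self._cds_ivals)
        if n != len(self.cds_seq):
            raise ValueError(
                f"cds_seq length {len(self.cds_seq)} != CDS interval total {n}"
            )
        # cumulative CDS offsets in transcription order for coordinate mapping
        order = self._cds_ivals if strand == "+" else self._cds_ivals[::-1]
        self._tx_order_ivals = order
        self._cum = np.cumsum([0] + [b - a + 1 for a, b in order])

    def _compute_cds_intervals(self) -> list[tuple[int, int]]:
        out = []
        for a, b in self.exons:
            lo, hi = max(a, self.cds_start), min(b, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        if not out:
            raise ValueError("CDS overlaps no exon")
        return out

    @property
    def cds_intervals(self) -> list[tuple[int, int]]:
        """CDS sub-intervals in genomic order (1-based inclusive)."""
        return list(self._cds_ivals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    def genomic_to_cds(self, gpos: int) -> int | None:
        """1-based CDS coordinate of a genomic position, or None if non-coding."""
        for k, (a, b) in enumerate(self._tx_order_ivals):
            if a <= gpos <= b:
                offset = (gpos - a) if self.strand == "+" else (b - gpos)
                return int(self._cum[k]) + offset + 1
        return None

    def cds_to_genomic(self, cpos: int) -> int:
        """Genomic position of 1-based CDS coordinate ``cpos``."""
        if not 1 <= cpos <= self.cds_length:
            raise ValueError(f"CDS position {cpos} outside 1..{self.cds_length}")
        k = bisect.bisect_right(self._cum, cpos - 1) - 1
        a, b = self._tx_order_ivals[k]
        offset = cpos - 1 - int(self._cum[k])
        return a + offset if self.strand == "+" else b - offset

    def intron_intervals(self) -> list[tuple[int, int]]:
        return [
            (b1 + 1, a2 - 1) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
        ]

    def in_exon(self, gpos: int) -> bool:
        return any(a <= gpos <= b for a, b in self.exons)


@dataclass(frozen=True)
class LiftoverBlock:
    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.src_start > self.src_end:
            raise ValueError("block src_start > src_end")
        if self.strand not in "+-":
            raise ValueError(f"bad block strand {self.strand!r}")

    def map(self, pos: int) -> tuple[str, int]:
        if self.strand == "+":
            return (self.tgt_chrom, self.tgt_start + (pos - self.src_start))
        return (self.tgt_chrom, self.tgt_start + (self.src_end - pos))


class LiftoverMap:
    """Blockwise affine coordinate map between two assemblies."""

    def __init__(self, blocks: list[LiftoverBlock]):
        by_chrom: dict[str, list[LiftoverBlock]] = {}
        for b in blocks:
            by_chrom.setdefault(b.src_chrom, []).append(b)
        for chrom, bl in by_chrom.items():
            bl.sort(key=lambda b: b.src_start)
            for b1, b2 in zip(bl, bl[1:]):
                if b2.src_start <= b1.src_end:
                    raise ValueError(
                        f"overlapping source blocks on {chrom}: "
                        f"{(b1.src_start, b1.src_end)} and {(b2.src_start, b2.src_end)}"
                    )
        self.blocks = [b for chrom in sorted(by_chrom) for b in by_chrom[chrom]]
        self._by_chrom = by_chrom
        self._starts = {c: [b.src_start for b in bl] for c, bl in by_chrom.items()}

    def __len__(self) -> int:
        return len(self.blocks)

    def map_position(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Map a source position; None if it falls outside every block."""
        bl = self._by_chrom.get(chrom)
        if not bl:
            return None
        k = bisect.bisect_right(self._starts[chrom], pos) - 1
        if k >= 0 and bl[k].src_start <= pos <= bl[k].src_end:
            return bl[k].map(pos)
        return None
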