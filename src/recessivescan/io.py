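"""Readers and writers for the standard formats the pipeline touches.

VCF parsing goes through :mod:`pysam`; gene models through :mod:`gffutils`;
FASTA through :mod:`pyfaidx`; tabular files through :mod:`pandas`.  All
coordinates in files are 1-based inclusive; the in-memory model keeps the
same convention, so no conversion logic lives outside this module.

Multiallelic VCF records are split into biallelic :class:`~recessivescan.model.Variant`
records on read: each ALT becomes its own variant, and a genotype that
references a *different* ALT at the same site becomes ``missing`` for the
split record.  This matches common decomposition semantics and keeps the
zygosity vocabulary closed.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    LiftoverBlock,
    LiftoverMap,
    SampleSheet,
    TranscriptModel,
    Variant,
)

TOOL_TAG = "recessivescan"


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _split_genotype(gt: tuple, alt_index: int) -> int:
    """Zygosity of one sample for one ALT of a (possibly multiallelic) record.

    ``gt`` is the pysam allele-index tuple; ``alt_index`` is 1-based.
    """
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return MISSING
    if len(gt) != 2 or any(a is None for a in gt):
        raise FormatError(f"non-diploid genotype {gt}")
    if any(a not in (0, alt_index) for a in gt):
        return MISSING  # references another ALT allele at this site
    return int(sum(a == alt_index for a in gt))


def read_vcf(path: str) -> tuple[list[Variant], GenotypeMatrix]:
    """Read a VCF 4.2 file into (variants, genotype matrix).

    Multiallelic records are split (see module docstring).  Only GT is used;
    QUAL/FILTER/INFO and other FORMAT fields are ignored.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vf.header.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    with vf:
        for rec in vf:
            if rec.alts is None:
                continue
            for j, alt in enumerate(rec.alts, start=1):
                col = np.empty(len(samples), dtype=np.int8)
                for i, s in enumerate(samples):
                    fmt = rec.samples[s]
                    if "GT" not in fmt:
                        raise FormatError(f"GT absent at {rec.chrom}:{rec.pos}")
                    col[i] = _split_genotype(fmt["GT"], j)
                variants.append(
                    Variant(rec.chrom, rec.pos, rec.ref.upper(), alt.upper(), rec.id)
                )
                columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return variants, GenotypeMatrix(samples, variants, calls)


_GT_TEXT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    variants: list[Variant],
    matrix: GenotypeMatrix | None,
    path: str,
    source: str | None = None,
) -> None:
    """Write biallelic variants (+ optional genotypes) as an uncompressed VCF 4.2.

    Round-trips through :func:`read_vcf`: calls and variant records are
    reproduced exactly.
    """
    samples = matrix.sample_ids if matrix is not None else []
    chroms = list(dict.fromkeys(v.chrom for v in variants))
    lines = ["##fileformat=VCFv4.2"]
    lines.append(f"##source={TOOL_TAG}" + (f" {source}" if source else ""))
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header += ["FORMAT"] + samples
    lines.append("\t".join(header))
    for j, v in enumerate(variants):
        row = [v.chrom, str(v.pos), v.id or ".", v.ref, v.alt, ".", ".", "."]
        if samples:
            row.append("GT")
            row.extend(_GT_TEXT[int(c)] for c in matrix.calls[:, j])
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta(path: str) -> Fasta:
    """Open an indexed FASTA (pyfaidx builds the .fai on first use)."""
    return Fasta(path, as_raw=True, sequence_always_upper=True)


def fetch_sequence(fasta: Fasta, chrom: str, start: int, end: int) -> str:
    """1-based inclusive fetch."""
    return str(fasta[chrom][start - 1 : end])


# ---------------------------------------------------------------------------
# Gene model (GFF3)
# ---------------------------------------------------------------------------

def read_gene_model(path: str, reference: str | Fasta) -> TranscriptModel:
    """Read a one-transcript GFF3 gene model and splice its CDS from the reference.

    The spliced CDS is assembled in transcription order (minus-strand models
    are reverse-complemented).  Raises :class:`FormatError` if the CDS length
    is not a multiple of 3 or the CDS does not end with a stop codon.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    mrnas = list(db.features_of_type("mRNA"))
    if len(mrnas) != 1:
        raise FormatError(f"expected exactly one mRNA feature, found {len(mrnas)}")
    mrna = mrnas[0]
    exons = sorted(
        (f.start, f.end) for f in db.children(mrna, featuretype="exon")
    )
    cds_rows = sorted(
        (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
    )
    if not exons or not cds_rows:
        raise FormatError("gene model needs exon and CDS features")
    cds_start = cds_rows[0][0]
    cds_end = cds_rows[-1][1]
    fasta = reference if isinstance(reference, Fasta) else open_fasta(reference)
    pieces = []
    for a, b in cds_rows:
        pieces.append(fetch_sequence(fasta, mrna.seqid, a, b))
    spliced = "".join(pieces)
    if mrna.strand == "-":
        from .model import revcomp

        spliced = revcomp(spliced)
    if len(spliced) % 3 != 0:
        raise FormatError(f"CDS length {len(spliced)} not divisible by 3")
    if spliced[-3:] not in ("TAA", "TAG", "TGA"):
        raise FormatError(f"CDS does not end with a stop codon ({spliced[-3:]})")
    return TranscriptModel(
        chrom=mrna.seqid,
        strand=mrna.strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        cds_seq=spliced,
        gene_id=mrna.attributes.get("Parent", ["gene1"])[0],
        transcript_id=mrna.id,
    )


def write_gene_model(tx: TranscriptModel, path: str, source: str | None = None) -> None:
    """Write a TranscriptModel as GFF3 (gene/mRNA/exon/CDS rows, CDS phase set)."""
    lines = ["##gff-version 3", f"# producer: {TOOL_TAG}" + (f" {source}" if source else "")]
    g0, g1 = tx.span

    def row(ftype, a, b, attrs, phase="."):
        return "\t".join(
            [tx.chrom, TOOL_TAG, ftype, str(a), str(b), ".", tx.strand, phase, attrs]
        )

    lines.append(row("gene", g0, g1, f"ID={tx.gene_id}"))
    lines.append(row("mRNA", g0, g1, f"ID={tx.transcript_id};Parent={tx.gene_id}"))
    for i, (a, b) in enumerate(tx.exons, start=1):
        lines.append(
            row("exon", a, b, f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}")
        )
    # phase: number of bases to skip to reach the next codon start
    ivals = tx.cds_intervals
    order = ivals if tx.strand == "+" else ivals[::-1]
    consumed = 0
    phases = {}
    for a, b in order:
        phases[(a, b)] = (3 - consumed % 3) % 3
        consumed += b - a + 1
    for i, (a, b) in enumerate(ivals, start=1):
        lines.append(
            row(
                "CDS",
                a,
                b,
                f"ID={tx.transcript_id}.cds{i};Parent={tx.transcript_id}",
                str(phases[(a, b)]),
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str) -> SampleSheet:
    """Read a TSV sample sheet (sample_id, role, breed, histology_label)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise FormatError(f"empty sample sheet {path}")
    required = {"sample_id", "role"}
    if not required <= set(df.columns):
        raise FormatError(f"sample sheet missing columns {required - set(df.columns)}")
    if "breed" not in df.columns:
        df["breed"] = "unknown"
    if "histology_label" not in df.columns:
        df["histology_label"] = "none"
    ids = df["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in sheet")
    return SampleSheet(
        sample_ids=ids,
        roles=dict(zip(ids, df["role"])),
        breeds=dict(zip(ids, df["breed"].fillna("unknown"))),
        histology=dict(zip(ids, df["histology_label"].fillna("none"))),
    )


def write_sample_sheet(sheet: SampleSheet, path: str, source: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# producer: {TOOL_TAG}" + (f" {source}" if source else "") + "\n")
        fh.write("sample_id\trole\tbreed\thistology_label\n")
        for s in sheet.sample_ids:
            fh.write(
                f"{s}\t{sheet.roles[s]}\t{sheet.breeds[s]}\t{sheet.histology.get(s, 'none')}\n"
            )


# ---------------------------------------------------------------------------
# Liftover block map
# ---------------------------------------------------------------------------

_LIFTOVER_COLS = ["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "strand"]


def read_liftover_map(path: str) -> LiftoverMap:
    """Read a TSV block map (src_chrom, src_start, src_end, tgt_chrom, tgt_start, strand).

    Intervals are 1-based inclusive.  Unicode minus signs are accepted for
    the strand column.  Overlapping source blocks raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_LIFTOVER_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"liftover map missing columns {missing}")
    blocks = []
    for row in df.itertuples(index=False):
        strand = str(row.strand).replace("−", "-")
        blocks.append(
            LiftoverBlock(
                src_chrom=str(row.src_chrom),
                src_start=int(row.src_start),
                src_end=int(row.src_end),
                tgt_chrom=str(row.tgt_chrom),
                tgt_start=int(row.tgt_start),
                strand=strand,
            )
        )
    try:
        return LiftoverMap(blocks)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_liftover_map(lmap: LiftoverMap, path: str, source: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# producer: {TOOL_TAG}" + (f" {source}" if source else "") + "\n")
        fh.write("\t".join(_LIFTOVER_COLS) + "\n")
        for b in lmap.blocks:
            fh.write(
                f"{b.src_chrom}\t{b.src_start}\t{b.src_end}\t"
                f"{b.tgt_chrom}\t{b.tgt_start}\t{b.strand}\n"
            )


# ---------------------------------------------------------------------------
# Array genotypes (sample x SNP dosage codes 0/1/2/NA)
# ---------------------------------------------------------------------------

def read_array_genotypes(path: str) -> pd.DataFrame:
    """Sample x SNP matrix of alt-allele dosages (float, NaN for no-calls)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    return df.astype(float)


def write_array_genotypes(df: pd.DataFrame, path: str, source: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# producer: {TOOL_TAG}" + (f" {source}" if source else "") + "\n")
        out = df.copy()
        out.index.name = "sample_id"
        text = out.to_csv(sep="\t", na_rep="NA", float_format="%.0f")
        fh.write(text)


def read_snp_map(path: str) -> pd.DataFrame:
    """SNP map TSV: snp_id, chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "chrom": str})
    df["pos"] = df["pos"].astype(int)
    return df


def write_snp_map(df: pd.DataFrame, path: str, source: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# producer: {TOOL_TAG}" + (f" {source}" if source else "") + "\n")
        df.to_csv(fh, sep="\t", index=False)
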