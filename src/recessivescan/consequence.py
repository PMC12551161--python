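"""Transcript-based consequence annotation with HGVS nomenclature.

Variants are classified against a single :class:`~recessivescan.model.TranscriptModel`
into one of ten consequence types, each mapped to a fixed impact class:

====================  ========
consequence           impact
====================  ========
frameshift            HIGH
stop_gained           HIGH
stop_lost             HIGH
splice_site           HIGH
missense              MODERATE
inframe_indel         MODERATE
synonymous            LOW
intronic              MODIFIER
utr                   MODIFIER
intergenic            MODIFIER
====================  ========

Frameshift deletions additionally receive truncation statistics obtained by
re-translating the mutant coding sequence: the first altered codon, the
number of novel residues read in the shifted frame before the premature stop
(``fs*N`` means the stop is the N-th codon counting the first altered codon
as 1, so there are N-1 novel residues), the number of wildtype C-terminal
residues the new tail replaces, and the replaced fraction of the protein.

HGVS conventions implemented here: deletions are shifted to their most-3'
position in the coding sequence before rendering ``c.`` notation (VCF
left-aligns, HGVS right-aligns); when the first frameshifted codon happens
to encode the wildtype residue the annotation advances to the next differing
residue; a frameshift whose first altered codon is itself a stop is rendered
as a nonsense change ``p.(Xaa#*)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .model import COMPLEMENT, TranscriptModel, Variant

IMPACT_TABLE = {
    "frameshift": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "splice_site": "HIGH",
    "missense": "MODERATE",
    "inframe_indel": "MODERATE",
    "synonymous": "LOW",
    "intronic": "MODIFIER",
    "utr": "MODIFIER",
    "intergenic": "MODIFIER",
}

IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}

SPLICE_WINDOW = 2  # bases into the intron counted as splice site

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)  # {'TAA','TAG','TGA'}


@dataclass
class ConsequenceCall:
    """Annotation of one variant against one transcript."""

    consequence: str
    impact: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    first_affected_codon: int | None = None
    novel_aa_count: int | None = None
    replaced_cterm_count: int | None = None
    percent_shorter: float | None = None

    def __post_init__(self) -> None:
        expected = IMPACT_TABLE[self.consequence]
        if self.impact != expected:
            raise ValueError(
                f"impact {self.impact} inconsistent with {self.consequence} "
                f"(expected {expected})"
            )


def translate(cds_seq: str) -> str:
    """Translate DNA to protein with the standard genetic code.

    Translation proceeds codon by codon up to the last complete codon and
    stops at the first stop codon; the stop itself is not returned.  Raises
    ``ValueError`` on non-ACGT characters.
    """
    seq = cds_seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in CDS: {sorted(set(seq) - set('ACGT'))}")
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            break
        out.append(_CODON_TABLE[codon])
    return "".join(out)


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def normalize_deletion(sequence: str, start: int, end: int) -> tuple[int, int]:
    """Shift a deletion of ``sequence[start..end]`` (1-based inclusive) 3'-most.

    HGVS requires the most-3' representation of an indel in a repeat
    context; VCF records are left-aligned.  The shifted interval deletes an
    identical multiset of bases: re-applying either deletion yields the same
    sequence.  Raises ``ValueError`` when the interval is out of range.
    """
    n = len(sequence)
    if not (1 <= start <= end <= n):
        raise ValueError(f"deletion {start}..{end} outside sequence of length {n}")
    while end < n and sequence[start - 1] == sequence[end]:
        start += 1
        end += 1
    return start, end


def map_genomic_to_cds(tx: TranscriptModel, gpos: int) -> int | str:
    """1-based CDS coordinate for coding positions, else a region label.

    Returns an ``int`` for positions in the spliced CDS and one of the
    strings ``"intronic"``, ``"utr"``, ``"intergenic"`` otherwise.
    """
    cpos = tx.genomic_to_cds(gpos)
    if cpos is not None:
        return cpos
    lo, hi = tx.span
    if gpos < lo or gpos > hi:
        return "intergenic"
    if tx.in_exon(gpos):
        return "utr"
    return "intronic"


def _near_splice(tx: TranscriptModel, positions: list[int]) -> bool:
    """True if any position sits in the first/last SPLICE_WINDOW bp of an intron."""
    for a, b in tx.intron_intervals():
        for g in positions:
            if a <= g <= min(b, a + SPLICE_WINDOW - 1):
                return True
            if max(a, b - SPLICE_WINDOW + 1) <= g <= b:
                return True
    return False


def _strand_base(tx: TranscriptModel, base: str) -> str:
    return base if tx.strand == "+" else base.translate(COMPLEMENT)


def _cds_positions_of(tx: TranscriptModel, gpositions: list[int]) -> list[int]:
    return sorted(
        c for c in (tx.genomic_to_cds(g) for g in gpositions) if c is not None
    )


def _wt_protein(tx: TranscriptModel) -> str:
    return translate(tx.cds_seq)


def _apply_cds_deletion(cds: str, cpositions: list[int]) -> str:
    drop = set(c - 1 for c in cpositions)
    return "".join(b for i, b in enumerate(cds) if i not in drop)


def _snv_call(tx: TranscriptModel, variant: Variant, cpos: int) -> ConsequenceCall:
    cds = tx.cds_seq
    ref_t = _strand_base(tx, variant.ref)
    alt_t = _strand_base(tx, variant.alt)
    if cds[cpos - 1] != ref_t:
        raise ValueError(
            f"reference mismatch at c.{cpos}: CDS has {cds[cpos - 1]}, variant REF "
            f"is {variant.ref} ({ref_t} on the coding strand)"
        )
    codon_idx = (cpos - 1) // 3  # 0-based
    frame = (cpos - 1) % 3
    ref_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:frame] + alt_t + ref_codon[frame + 1 :]
    hgvs_c = f"c.{cpos}{ref_t}>{alt_t}"
    ref_is_stop = ref_codon in _STOPS
    alt_is_stop = alt_codon in _STOPS
    pos1 = codon_idx + 1
    if ref_is_stop and not alt_is_stop:
        cons = "stop_lost"
        hgvs_p = f"p.(Ter{pos1}{_aa3(_CODON_TABLE[alt_codon])}ext*?)"
    elif alt_is_stop and not ref_is_stop:
        cons = "stop_gained"
        hgvs_p = f"p.({_aa3(_CODON_TABLE[ref_codon])}{pos1}*)"
    elif ref_is_stop and alt_is_stop:
        cons = "synonymous"
        hgvs_p = f"p.(Ter{pos1}=)"
    else:
        ref_aa = _CODON_TABLE[ref_codon]
        alt_aa = _CODON_TABLE[alt_codon]
        if ref_aa == alt_aa:
            cons = "synonymous"
            hgvs_p = f"p.({_aa3(ref_aa)}{pos1}=)"
        else:
            cons = "missense"
            hgvs_p = f"p.({_aa3(ref_aa)}{pos1}{_aa3(alt_aa)})"
    return ConsequenceCall(cons, IMPACT_TABLE[cons], hgvs_c, hgvs_p)


def classify_consequence(tx: TranscriptModel, variant: Variant) -> ConsequenceCall:
    """Classify a variant against the transcript and assign its impact class.

    SNVs inside the CDS are compared codon-wise.  Indels whose removed (or
    inserted) length is a multiple of 3 and that lie entirely within the CDS
    are ``inframe_indel``; any other CDS-overlapping indel is ``frameshift``
    (truncation statistics are added by :func:`annotate_frameshift`).
    Positions within 2 bp of an intron boundary are ``splice_site``.
    """

    def modifier(label: str) -> ConsequenceCall:
        return ConsequenceCall(label, IMPACT_TABLE[label])

    if variant.chrom != tx.chrom:
        return modifier("intergenic")

    if variant.is_snv:
        region = map_genomic_to_cds(tx, variant.pos)
        if isinstance(region, int):
            return _snv_call(tx, variant, region)
        if _near_splice(tx, [variant.pos]):
            return ConsequenceCall("splice_site", "HIGH")
        return modifier(region)

    # indel: genomic bases touched (excluding the anchor base)
    if variant.is_deletion:
        a, b = variant.deleted_span()
        touched = list(range(a, b + 1))
    elif variant.is_insertion:
        touched = [variant.pos, variant.pos + 1]
    else:  # complex substitution: treat like a deletion of the REF tail
        touched = list(range(variant.pos, variant.pos + len(variant.ref)))

    cds_hits = _cds_positions_of(tx, touched)
    if cds_hits:
        if variant.is_deletion:
            net = len(cds_hits)
            entirely_cds = len(cds_hits) == len(touched)
        elif variant.is_insertion:
            net = len(variant.alt) - 1
            entirely_cds = all(tx.genomic_to_cds(g) is not None for g in touched)
        else:
            net = abs(len(variant.alt) - len(variant.ref))
            entirely_cds = len(cds_hits) == len(touched)
        if net % 3 == 0 and entirely_cds:
            cons = "inframe_indel"
        else:
            cons = "frameshift"
        return ConsequenceCall(cons, IMPACT_TABLE[cons])
    if _near_splice(tx, touched):
        return ConsequenceCall("splice_site", "HIGH")
    labels = {map_genomic_to_cds(tx, g) for g in touched}
    for label in ("intronic", "utr", "intergenic"):
        if label in labels:
            return modifier(label)
    return modifier("intergenic")


def annotate_frameshift(tx: TranscriptModel, variant: Variant) -> ConsequenceCall:
    """Complete a frameshift deletion call with HGVS p-notation and truncation stats.

    The wildtype and mutant coding sequences are both translated in full and
    compared residue by residue.  With the first differing residue at codon
    ``d`` and the premature stop at new-frame position ``N`` (1-based,
    counting codon ``d`` as 1) the call reports::

        hgvs_p               = p.(RefAA{d}AltAAfs*N)
        first_affected_codon = d
        novel_aa_count       = N - 1
        replaced_cterm_count = len(wildtype protein) - d + 1
        percent_shorter      = replaced_cterm_count / len(wildtype protein)

    A mutant CDS with no downstream stop is reported as ``fs*?`` with
    ``novel_aa_count`` None.
    """
    base = classify_consequence(tx, variant)
    if base.consequence != "frameshift":
        raise ValueError(f"variant is {base.consequence}, not frameshift")
    if not variant.is_deletion:
        raise NotImplementedError("truncation statistics implemented for deletions")

    a, b = variant.deleted_span()
    cds_hits = _cds_positions_of(tx, list(range(a, b + 1)))
    # HGVS c.: 3'-shift the deletion within the CDS when the removed run is contiguous
    c_lo, c_hi = min(cds_hits), max(cds_hits)
    if c_hi - c_lo + 1 == len(cds_hits):
        c_lo, c_hi = normalize_deletion(tx.cds_seq, c_lo, c_hi)
        del_positions = list(range(c_lo, c_hi + 1))
    else:
        del_positions = cds_hits
    hgvs_c = f"c.{c_lo}del" if c_lo == c_hi else f"c.{c_lo}_{c_hi}del"

    wt_cds = tx.cds_seq
    mut_cds = _apply_cds_deletion(wt_cds, del_positions)
    wt_protein = translate(wt_cds)
    mut_protein = translate(mut_cds)
    mut_has_stop = any(
        mut_cds[i : i + 3] in _STOPS
        for i in range(0, len(mut_cds) - len(mut_cds) % 3, 3)
    )

    # first residue that differs between the two translations (HGVS scan rule)
    d = None
    for i in range(min(len(wt_protein), len(mut_protein))):
        if wt_protein[i] != mut_protein[i]:
            d = i + 1
            break
    if d is None:
        d = min(len(wt_protein), len(mut_protein)) + 1

    wt_len = len(wt_protein)
    replaced = wt_len - d + 1
    pct = replaced / wt_len if wt_len else None

    if d > len(mut_protein):
        # the first change is the premature stop itself: nonsense-style notation
        ref_aa = wt_protein[d - 1] if d <= wt_len else "*"
        hgvs_p = f"p.({_aa3(ref_aa)}{d}*)"
        novel = 0
    else:
        ref_aa = wt_protein[d - 1] if d <= wt_len else "*"
        alt_aa = mut_protein[d - 1]
        if mut_has_stop:
            stop_offset = len(mut_protein) - d + 2  # stop position in new frame
            hgvs_p = f"p.({_aa3(ref_aa)}{d}{_aa3(alt_aa)}fs*{stop_offset})"
            novel = stop_offset - 1
        else:
            hgvs_p = f"p.({_aa3(ref_aa)}{d}{_aa3(alt_aa)}fs*?)"
            novel = None

    return ConsequenceCall(
        consequence="frameshift",
        impact="HIGH",
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        first_affected_codon=d,
        novel_aa_count=novel,
        replaced_cterm_count=replaced,
        percent_shorter=pct,
    )


def annotate(tx: TranscriptModel, variant: Variant) -> ConsequenceCall:
    """Classify, and complete frameshift deletions with truncation statistics."""
    call = classify_consequence(tx, variant)
    if call.consequence == "frameshift" and variant.is_deletion:
        return annotate_frameshift(tx, variant)
    return call
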