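"""Consequence annotation: coordinate mapping, translation, HGVS frameshift arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recessivescan.consequence import (
    IMPACT_TABLE,
    annotate_frameshift,
    classify_consequence,
    map_genomic_to_cds,
    normalize_deletion,
    translate,
)
from recessivescan.model import TranscriptModel, Variant, revcomp

HYPO = settings(max_examples=30, deadline=None, derandomize=True)

# independent codon table (oracle), written out rather than imported
ORACLE_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE = sorted(c for c, aa in ORACLE_CODONS.items() if aa != "*")

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def oracle_translate(seq):
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = ORACLE_CODONS[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def oracle_frameshift(wt_cds, del_start, del_len):
    """Full re-translation diff oracle: translate both sequences, diff residues.

    Returns (first_affected_codon, ref_aa, alt_aa_or_None, stop_offset_or_None,
    mutant_has_stop).
    """
    mut = wt_cds[: del_start - 1] + wt_cds[del_start - 1 + del_len :]
    wt_p = oracle_translate(wt_cds)
    mut_p = oracle_translate(mut)
    has_stop = any(
        ORACLE_CODONS[mut[i : i + 3]] == "*"
        for i in range(0, len(mut) - len(mut) % 3, 3)
    )
    d = None
    for i in range(min(len(wt_p), len(mut_p))):
        if wt_p[i] != mut_p[i]:
            d = i + 1
            break
    if d is None:
        d = min(len(wt_p), len(mut_p)) + 1
    ref_aa = wt_p[d - 1] if d <= len(wt_p) else "*"
    if d > len(mut_p):
        return d, ref_aa, None, 1 if has_stop else None, has_stop
    stop_offset = len(mut_p) - d + 2 if has_stop else None
    return d, ref_aa, mut_p[d - 1], stop_offset, has_stop


def single_exon_tx(cds, offset=1000, chrom="chrT"):
    return TranscriptModel(
        chrom, "+", [(offset + 1, offset + len(cds))], offset + 1, offset + len(cds), cds
    )


def random_cds(rng, n_codons):
    body = "".join(SENSE[int(rng.integers(len(SENSE)))] for _ in range(n_codons))
    return body + "TAA"


class TestMapGenomicToCds:
    def toy(self, strand):
        # exons (101-150),(201-250), CDS = all exonic bases (100 nt)
        plus_cds = ("ATGAAACCCGGGTTTACGGC" * 5)[:100]
        cds_seq = plus_cds if strand == "+" else revcomp(plus_cds)
        return TranscriptModel("chrT", strand, [(101, 150), (201, 250)], 101, 250, cds_seq)

    def test_plus_strand_hand_counts(self):
        tx = self.toy("+")
        assert map_genomic_to_cds(tx, 120) == 20
        assert map_genomic_to_cds(tx, 101) == 1
        assert map_genomic_to_cds(tx, 201) == 51

    def test_between_exons_is_intronic(self):
        assert map_genomic_to_cds(self.toy("+"), 175) == "intronic"

    def test_minus_strand_hand_counts(self):
        tx = self.toy("-")
        assert map_genomic_to_cds(tx, 250) == 1
        assert map_genomic_to_cds(tx, 101) == 100

    def test_outside_gene_is_intergenic(self):
        assert map_genomic_to_cds(self.toy("+"), 50) == "intergenic"


class TestTranslate:
    def test_examples(self):
        assert translate("ATGAAATAG") == "MK"
        assert translate("") == ""
        assert translate("ATGAA") == "M"  # trailing partial codon ignored

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGNNN")

    @HYPO
    @given(seed=st.integers(0, 10_000))
    def test_random_sequences_match_codon_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.random.default_rng(seed).choice(list("ACGT"), 300))
        assert translate(seq) == oracle_translate(seq)


class TestNormalizeDeletion:
    def test_shifts_to_three_prime_most_copy(self):
        assert normalize_deletion("AACCT", 3, 3) == (4, 4)

    def test_no_repeat_context_unchanged(self):
        assert normalize_deletion("AGCTT", 2, 2) == (2, 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_deletion("ACGT", 3, 9)

    @HYPO
    @given(seed=st.integers(0, 10_000))
    def test_shifted_deletion_yields_identical_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACG"), 40))  # 3-letter alphabet: many repeats
        start = int(rng.integers(1, 38))
        end = min(40, start + int(rng.integers(0, 3)))
        s2, e2 = normalize_deletion(seq, start, end)
        apply = lambda a, b: seq[: a - 1] + seq[b:]
        assert apply(s2, e2) == apply(start, end)
        assert e2 - s2 == end - start


class TestClassifyConsequence:
    def test_planted_two_bp_deletion_is_high_impact_frameshift(
        self, default_dataset, default_tx
    ):
        t = default_dataset.truth["causal"]
        call = classify_consequence(
            default_tx, Variant(t["chrom"], t["pos"], t["ref"], t["alt"])
        )
        assert call.consequence == "frameshift" and call.impact == "HIGH"

    def test_asn_to_ser_snv_is_moderate_missense(self):
        # mirrors c.215A>G p.(Asn72Ser): here a toy AAT->AGT at codon 2
        cds = "ATGAATCCC" + "TAA"
        tx = single_exon_tx(cds)
        call = classify_consequence(tx, Variant("chrT", 1005, "A", "G"))
        assert (call.consequence, call.impact) == ("missense", "MODERATE")
        assert call.hgvs_p == "p.(Asn2Ser)"
        assert call.hgvs_c == "c.5A>G"

    def test_third_position_synonymous_snv_is_low(self):
        cds = "ATGAAACCC" + "TAA"
        tx = single_exon_tx(cds)
        call = classify_consequence(tx, Variant("chrT", 1006, "A", "G"))  # AAA->AAG Lys
        assert (call.consequence, call.impact) == ("synonymous", "LOW")

    def test_stop_gained_snv(self):
        cds = "ATGTACCCC" + "TAA"  # TAC Tyr -> TAA stop via C>A at cds 6
        tx = single_exon_tx(cds)
        call = classify_consequence(tx, Variant("chrT", 1006, "C", "A"))
        assert (call.consequence, call.impact) == ("stop_gained", "HIGH")

    def test_inframe_deletion_is_moderate(self):
        cds = "ATGAAACCCGGG" + "TAA"
        tx = single_exon_tx(cds)
        # delete cds 4-6 (AAA): anchor at cds 3
        call = classify_consequence(tx, Variant("chrT", 1003, "GAAA", "G"))
        assert (call.consequence, call.impact) == ("inframe_indel", "MODERATE")

    def test_splice_site_and_intronic_and_utr(self):
        # exons (101,150),(201,251); CDS 111..251 (101-110 is 5' UTR): 91 nt
        plus_cds = ("ATGAAACCCGGGTTTACGGC" * 5)[:91]
        tx = TranscriptModel("chrT", "+", [(101, 150), (201, 251)], 111, 251, plus_cds)
        assert classify_consequence(tx, Variant("chrT", 152, "A", "T")).consequence == "splice_site"
        assert classify_consequence(tx, Variant("chrT", 199, "A", "T")).consequence == "splice_site"
        assert classify_consequence(tx, Variant("chrT", 170, "A", "T")).consequence == "intronic"
        assert classify_consequence(tx, Variant("chrT", 105, "A", "T")).consequence == "utr"
        assert classify_consequence(tx, Variant("chrT", 2, "A", "T")).consequence == "intergenic"

    def test_impact_table_is_total(self):
        assert set(IMPACT_TABLE.values()) == {"HIGH", "MODERATE", "LOW", "MODIFIER"}
        assert len(IMPACT_TABLE) == 10


class TestAnnotateFrameshift:
    def test_worked_example_on_synthetic_transcript(self, default_dataset, default_tx):
        t = default_dataset.truth["causal"]
        call = annotate_frameshift(
            default_tx, Variant(t["chrom"], t["pos"], t["ref"], t["alt"])
        )
        assert call.hgvs_p == "p.(Leu1380Glyfs*17)"
        assert call.hgvs_c == "c.4138_4139del"
        assert call.first_affected_codon == 1380
        assert call.novel_aa_count == 16
        assert call.replaced_cterm_count == 287
        assert call.percent_shorter == pytest.approx(287 / 1666)

    def test_single_base_deletion_frameshifts_from_first_codon(self):
        cds = "ATGAAATAA"
        tx = single_exon_tx(cds)
        # delete cds 2 (T of ATG): anchor at cds 1
        call = annotate_frameshift(tx, Variant("chrT", 1001, "AT", "A"))
        assert call.consequence == "frameshift"
        assert call.first_affected_codon == 1

    def test_non_frameshift_input_rejected(self):
        cds = "ATGAAACCCTAA"
        tx = single_exon_tx(cds)
        with pytest.raises(ValueError):
            annotate_frameshift(tx, Variant("chrT", 1003, "GAAA", "G"))

    @HYPO
    @given(seed=st.integers(0, 10_000))
    def test_components_match_retranslation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cds = random_cds(rng, int(rng.integers(20, 60)))
        del_len = int(rng.choice([1, 2, 4, 5]))
        del_start = int(rng.integers(2, len(cds) - del_len))
        tx = single_exon_tx(cds)
        ref = cds[del_start - 2 : del_start - 1 + del_len]
        variant = Variant("chrT", 1000 + del_start - 1, ref, ref[0])
        call = annotate_frameshift(tx, variant)
        d, ref_aa, alt_aa, stop_offset, has_stop = oracle_frameshift(
            cds, del_start, del_len
        )
        assert call.first_affected_codon == d
        if alt_aa is None:  # first change is the premature stop itself
            assert call.novel_aa_count == 0
            assert call.hgvs_p.endswith(f"{d}*)")
        elif not has_stop:
            assert call.novel_aa_count is None
            assert call.hgvs_p.endswith("fs*?)")
        else:
            assert call.novel_aa_count == stop_offset - 1
            assert call.hgvs_p == f"p.({AA3[ref_aa]}{d}{AA3[alt_aa]}fs*{stop_offset})"

    @HYPO
    @given(seed=st.integers(0, 10_000))
    def test_inframe_deletion_never_called_frameshift(self, seed):
        rng = np.random.default_rng(seed)
        cds = random_cds(rng, 30)
        del_len = int(rng.choice([3, 6]))
        del_start = int(rng.integers(2, len(cds) - del_len - 3))
        tx = single_exon_tx(cds)
        ref = cds[del_start - 2 : del_start - 1 + del_len]
        call = classify_consequence(tx, Variant("chrT", 1000 + del_start - 1, ref, ref[0]))
        assert call.consequence != "frameshift"

    def test_first_affected_codon_lower_bound(self, default_dataset, default_tx):
        # for a deletion at CDS position d the first changed codon cannot
        # precede floor((d-1)/3)+1
        t = default_dataset.truth["causal"]
        d = t["cds_del_start"]
        call = annotate_frameshift(
            default_tx, Variant(t["chrom"], t["pos"], t["ref"], t["alt"])
        )
        assert call.first_affected_codon >= (d - 1) // 3 + 1
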