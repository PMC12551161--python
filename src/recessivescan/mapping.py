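"""Case/control association scan and runs-of-homozygosity mapping.

The association test is the two-sided Fisher exact test on the 2x2 allele
table (case alt / case ref / control alt / control ref), the deterministic
exact counterpart of a single-marker logistic fit at small case counts.
The two-sided p-value follows the conventional definition: the sum of
hypergeometric probabilities of all tables (with the observed margins) no
more probable than the observed one.

ROH detection uses the consecutive-runs method: maximal stretches of
homozygous calls tolerating a bounded number of heterozygotes, with limits
on inter-SNP gaps, minimum SNP count and minimum physical length.  Missing
calls are ignored (they neither extend nor break a run and do not count
toward ``min_snps``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .model import SampleSheet

SUGGESTIVE_NEG_LOG10_P = 5.0
GENOME_WIDE_NEG_LOG10_P = 8.0

# relative tolerance for "no more probable" ties, as used by R and scipy
_TIE_GAMMA = 1 + 1e-7


@dataclass
class AssociationResult:
    snp_id: str
    chrom: str
    pos: int
    p_value: float
    neg_log10_p: float
    counts: tuple[int, int, int, int]  # case_alt, case_ref, control_alt, control_ref
    flag: str  # none | suggestive | genome_wide


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het_inside: int


@dataclass
class ROHParams:
    min_snps: int = 30
    max_het: int = 1
    max_gap_bp: int = 1_000_000
    min_length_bp: int = 1_000_000


@lru_cache(maxsize=100_000)
def _hypergeom_pmf(n: int, alt_total: int, row1: int) -> tuple[int, np.ndarray]:
    """Exact hypergeometric pmf over the table support for fixed margins.

    Returns (support minimum, pmf array); probabilities are computed from
    integer binomial coefficients, so they are exact up to one float division.
    """
    lo = max(0, row1 - (n - alt_total))
    hi = min(row1, alt_total)
    denom = math.comb(n, row1)
    probs = np.array(
        [
            math.comb(alt_total, a) * math.comb(n - alt_total, row1 - a) / denom
            for a in range(lo, hi + 1)
        ]
    )
    return lo, probs


def allelic_test(case_alt: int, case_ref: int, control_alt: int, control_ref: int) -> float:
    """Two-sided Fisher exact p-value for a 2x2 allele table.

    Computed from the full hypergeometric distribution over tables with the
    observed margins: the p-value is the sum of probabilities of all tables
    no more probable than the observed one.  Raises ``ValueError`` for an
    all-zero table or negative counts.
    """
    a, b, c, d = case_alt, case_ref, control_alt, control_ref
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    lo, pmf = _hypergeom_pmf(n, a + c, a + b)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * _TIE_GAMMA].sum())
    return min(p, 1.0)


def _flag(neg_log10_p: float, suggestive: float, genome_wide: float) -> str:
    if neg_log10_p >= genome_wide:
        return "genome_wide"
    if neg_log10_p >= suggestive:
        return "suggestive"
    return "none"


def association_scan(
    genotypes: pd.DataFrame,
    snp_map: pd.DataFrame,
    sheet: SampleSheet,
    min_call_rate: float = 0.9,
    suggestive: float = SUGGESTIVE_NEG_LOG10_P,
    genome_wide: float = GENOME_WIDE_NEG_LOG10_P,
) -> list[AssociationResult]:
    """Single-marker allelic association across all array SNPs.

    ``genotypes``: sample x SNP alt-allele dosages (NaN for no-calls);
    ``snp_map``: snp_id / chrom / pos.  SNPs with call rate below
    ``min_call_rate`` are dropped.  Results are sorted by chrom, pos.
    """
    cases = [s for s in sheet.sample_ids if sheet.roles[s] == "case"]
    controls = [s for s in sheet.sample_ids if sheet.roles[s] == "array_control"]
    if not cases or not controls:
        raise ValueError("association scan needs both cases and controls")

    gt_cases = genotypes.loc[cases].to_numpy(dtype=float)
    gt_controls = genotypes.loc[controls].to_numpy(dtype=float)
    n_total = len(cases) + len(controls)
    called_cases = (~np.isnan(gt_cases)).sum(axis=0)
    called_controls = (~np.isnan(gt_controls)).sum(axis=0)
    call_rate = (called_cases + called_controls) / n_total
    case_alt = np.nansum(gt_cases, axis=0).astype(int)
    control_alt = np.nansum(gt_controls, axis=0).astype(int)

    meta = snp_map.set_index("snp_id").reindex(genotypes.columns)
    chrom_arr = meta["chrom"].astype(str).to_numpy()
    pos_arr = meta["pos"].astype(int).to_numpy()
    results: list[AssociationResult] = []
    for j, snp in enumerate(genotypes.columns):
        if call_rate[j] < min_call_rate:
            continue
        ca = int(case_alt[j])
        cr = int(2 * called_cases[j] - ca)
        oa = int(control_alt[j])
        orf = int(2 * called_controls[j] - oa)
        p = allelic_test(ca, cr, oa, orf)
        nlp = -math.log10(p) if p > 0 else math.inf
        results.append(
            AssociationResult(
                snp_id=snp,
                chrom=chrom_arr[j],
                pos=int(pos_arr[j]),
                p_value=p,
                neg_log10_p=nlp,
                counts=(ca, cr, oa, orf),
                flag=_flag(nlp, suggestive, genome_wide),
            )
        )
    results.sort(key=lambda r: (r.chrom, r.pos))
    return results


def detect_roh(
    positions: np.ndarray,
    calls: np.ndarray,
    params: ROHParams | None = None,
    sample_id: str = "sample",
    chrom: str = "chrom",
) -> list[ROHSegment]:
    """Consecutive-runs ROH detection on one sample/chromosome vector.

    ``calls`` are dosage codes (0/2 homozygous, 1 heterozygous, negative or
    NaN missing) aligned with sorted ``positions``.  A segment is a maximal
    window that starts and ends on a homozygous call, contains at most
    ``max_het`` heterozygotes, and has no gap between consecutive called
    SNPs exceeding ``max_gap_bp``; segments shorter than ``min_length_bp``
    or with fewer than ``min_snps`` called SNPs are discarded.  Overlapping
    maximal windows (distinct heterozygote subsets) are all reported.
    """
    params = params or ROHParams()
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    calls = np.asarray(calls, dtype=float)

    keep = ~np.isnan(calls) & (calls >= 0)
    pos = positions[keep]
    gt = calls[keep]
    if pos.size == 0:
        return []

    # split into blocks at gaps > max_gap_bp
    gap_break = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
    block_bounds = np.concatenate(([0], gap_break + 1, [pos.size]))

    segments: list[ROHSegment] = []
    for s, e in zip(block_bounds[:-1], block_bounds[1:]):
        bpos = pos[s:e]
        bgt = gt[s:e]
        het_idx = np.flatnonzero(bgt == 1)
        n = bpos.size

        windows: set[tuple[int, int]] = set()

        def trimmed(lo: int, hi: int) -> tuple[int, int] | None:
            while lo <= hi and bgt[lo] == 1:
                lo += 1
            while hi >= lo and bgt[hi] == 1:
                hi -= 1
            return (lo, hi) if lo <= hi else None

        m = het_idx.size
        if m <= params.max_het:
            w = trimmed(0, n - 1)
            if w:
                windows.add(w)
        else:
            for j in range(m - params.max_het + 1):
                lo = het_idx[j - 1] + 1 if j > 0 else 0
                hi = het_idx[j + params.max_het] - 1 if j + params.max_het < m else n - 1
                w = trimmed(lo, hi)
                if w:
                    windows.add(w)

        # drop windows contained in another (can arise after trimming)
        maximal = [
            w
            for w in windows
            if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in windows)
        ]
        for lo, hi in sorted(maximal):
            n_snps = hi - lo + 1
            length = int(bpos[hi] - bpos[lo] + 1)
            if n_snps < params.min_snps or length < params.min_length_bp:
                continue
            segments.append(
                ROHSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(bpos[lo]),
                    end=int(bpos[hi]),
                    n_snps=n_snps,
                    n_het_inside=int((bgt[lo : hi + 1] == 1).sum()),
                )
            )
    return segments


def roh_scan(
    genotypes: pd.DataFrame,
    snp_map: pd.DataFrame,
    sample_ids: list[str] | None = None,
    params: ROHParams | None = None,
) -> dict[str, list[ROHSegment]]:
    """Run :func:`detect_roh` per sample per chromosome."""
    params = params or ROHParams()
    sample_ids = sample_ids if sample_ids is not None else list(genotypes.index)
    out: dict[str, list[ROHSegment]] = {s: [] for s in sample_ids}
    order = snp_map.sort_values(["chrom", "pos"])
    for chrom, grp in order.groupby("chrom", sort=True):
        snps = grp["snp_id"].tolist()
        positions = grp["pos"].to_numpy()
        sub = genotypes.loc[sample_ids, snps].to_numpy(dtype=float)
        for i, s in enumerate(sample_ids):
            out[s].extend(
                detect_roh(positions, sub[i], params, sample_id=s, chrom=str(chrom))
            )
    return out


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in sorted(ivals):
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def shared_roh_region(
    segments_by_sample: dict[str, list[ROHSegment]],
    case_ids: list[str],
    min_share_fraction: float = 0.9,
) -> list[tuple[str, int, int]]:
    """Genomic intervals covered by an ROH in enough cases.

    Sweep-line over per-case merged ROH intervals; returns maximal
    non-overlapping (chrom, start, end) intervals where at least
    ``ceil(min_share_fraction * n_cases)`` cases are homozygous, sorted.
    """
    if not 0 < min_share_fraction <= 1:
        raise ValueError("min_share_fraction must be in (0, 1]")
    need = math.ceil(min_share_fraction * len(case_ids))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in case_ids:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for seg in segments_by_sample.get(s, []):
            per_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
        for chrom, ivals in per_chrom.items():
            by_chrom.setdefault(chrom, []).extend(_merge_intervals(ivals))

    shared: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        events: list[tuple[int, int]] = []
        for a, b in by_chrom[chrom]:
            events.append((a, +1))
            events.append((b + 1, -1))
        events.sort()
        cov = 0
        open_start: int | None = None
        raw: list[tuple[int, int]] = []
        for x, delta in events:
            prev = cov
            cov += delta
            if prev < need <= cov:
                open_start = x
            elif prev >= need > cov and open_start is not None:
                raw.append((open_start, x - 1))
                open_start = None
        shared.extend((chrom, a, b) for a, b in _merge_intervals(raw))
    return shared
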