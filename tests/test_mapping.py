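"""Association scan (exact allelic test) and runs-of-homozygosity detection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

import recessivescan.io as rio
from recessivescan.mapping import (
    ROHParams,
    ROHSegment,
    allelic_test,
    association_scan,
    detect_roh,
    roh_scan,
    shared_roh_region,
)
from recessivescan.model import SampleSheet


def roh_oracle(positions, calls, params):
    """Brute-force all-windows ROH oracle (quadratic scan over called SNPs)."""
    keep = [
        i
        for i, c in enumerate(calls)
        if not (isinstance(c, float) and math.isnan(c)) and c >= 0
    ]
    pos = [int(positions[i]) for i in keep]
    gt = [int(calls[i]) for i in keep]
    n = len(pos)
    het_prefix = [0]
    for g in gt:
        het_prefix.append(het_prefix[-1] + (g == 1))

    def valid(i, j):
        if gt[i] == 1 or gt[j] == 1:
            return False
        if het_prefix[j + 1] - het_prefix[i] > params.max_het:
            return False
        return all(pos[k + 1] - pos[k] <= params.max_gap_bp for k in range(i, j))

    windows = [(i, j) for i in range(n) for j in range(i, n) if valid(i, j)]
    maximal = [
        w
        for w in windows
        if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in windows)
    ]
    out = []
    for i, j in sorted(maximal):
        n_snps = j - i + 1
        length = pos[j] - pos[i] + 1
        if n_snps >= params.min_snps and length >= params.min_length_bp:
            out.append((pos[i], pos[j], n_snps, het_prefix[j + 1] - het_prefix[i]))
    return out


def segs_as_tuples(segments):
    return [(s.start, s.end, s.n_snps, s.n_het_inside) for s in segments]


class TestAllelicTest:
    def test_symmetric_table_gives_p_one(self):
        assert allelic_test(10, 10, 10, 10) == 1.0

    def test_small_table_enumeration(self):
        # margins fix 3 possible tables with probabilities 1/6, 4/6, 1/6;
        # the observed extreme table gives p = 1/6 + 1/6 = 1/3
        assert allelic_test(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            t = rng.integers(0, 30, size=4)
            if t.sum() == 0:
                continue
            ours = allelic_test(*map(int, t))
            ref = fisher_exact([[t[0], t[1]], [t[2], t[3]]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            allelic_test(0, 0, 0, 0)
        with pytest.raises(ValueError):
            allelic_test(-1, 2, 3, 4)


def array_fixture(seed=0, n_snps=300, n_cases=10, n_controls=40, assoc_block=None):
    rng = np.random.default_rng(seed)
    samples = [f"CASE{i:02d}" for i in range(n_cases)] + [
        f"CTRL{i:02d}" for i in range(n_controls)
    ]
    freqs = rng.uniform(0.1, 0.45, n_snps)
    geno = rng.binomial(2, freqs[None, :], size=(len(samples), n_snps)).astype(float)
    if assoc_block is not None:
        lo, hi = assoc_block
        geno[: n_cases - 1, lo:hi] = 2.0
    genotypes = pd.DataFrame(
        geno, index=samples, columns=[f"S{j:04d}" for j in range(n_snps)]
    )
    snp_map = pd.DataFrame(
        {
            "snp_id": genotypes.columns,
            "chrom": "chr1",
            "pos": 1000 * (np.arange(n_snps) + 1),
        }
    )
    sheet = SampleSheet(
        sample_ids=samples,
        roles={s: ("case" if s.startswith("CASE") else "array_control") for s in samples},
        breeds={s: "Merino" for s in samples},
        histology={s: "none" for s in samples},
    )
    return genotypes, snp_map, sheet


class TestAssociationScan:
    def test_planted_block_dominates(self):
        genotypes, snp_map, sheet = array_fixture(seed=3, assoc_block=(100, 120))
        results = association_scan(genotypes, snp_map, sheet)
        best = min(results, key=lambda r: r.p_value)
        assert 100_000 <= best.pos <= 120_000

    def test_low_call_rate_snp_dropped(self):
        genotypes, snp_map, sheet = array_fixture(seed=4, n_snps=20)
        genotypes.iloc[:30, 5] = np.nan  # 30/50 missing -> call rate 0.4
        results = association_scan(genotypes, snp_map, sheet)
        assert "S0005" not in [r.snp_id for r in results]
        assert len(results) == 19

    def test_requires_cases_and_controls(self):
        genotypes, snp_map, sheet = array_fixture(n_snps=10)
        sheet_no_cases = SampleSheet(
            sample_ids=sheet.sample_ids,
            roles={s: "array_control" for s in sheet.sample_ids},
            breeds=sheet.breeds,
            histology=sheet.histology,
        )
        with pytest.raises(ValueError):
            association_scan(genotypes, snp_map, sheet_no_cases)

    def test_permuted_labels_rarely_reach_suggestive_threshold(self, default_dataset):
        # with case/control labels permuted the planted signal vanishes; the
        # genome-wide minimum p should fall below the suggestive line almost
        # always (expected ~100% of permutations)
        genotypes = rio.read_array_genotypes(default_dataset.array_genotypes)
        snp_map = rio.read_snp_map(default_dataset.array_snp_map)
        sheet = rio.read_sample_sheet(default_dataset.array_sheet)
        rng = np.random.default_rng(11)
        n_cases = len([s for s in sheet.sample_ids if sheet.roles[s] == "case"])
        hits = 0
        n_perm = 100
        for _ in range(n_perm):
            perm = rng.permutation(sheet.sample_ids)
            roles = {
                s: ("case" if i < n_cases else "array_control")
                for i, s in enumerate(perm)
            }
            psheet = SampleSheet(
                sample_ids=sheet.sample_ids,
                roles=roles,
                breeds=sheet.breeds,
                histology=sheet.histology,
            )
            results = association_scan(genotypes, snp_map, psheet)
            max_nlp = max(r.neg_log10_p for r in results)
            if max_nlp < 5.0:
                hits += 1
        assert hits >= 0.95 * n_perm


class TestDetectROH:
    PARAMS = ROHParams(min_snps=30, max_het=1, max_gap_bp=1_000_000, min_length_bp=1_000_000)

    def test_long_homozygous_run_flanked_by_hets(self):
        positions = np.arange(50 + 2) * 40_000  # 40 kb spacing, ~2 Mb run
        calls = np.array([1] + [0] * 50 + [1], dtype=float)
        segs = detect_roh(positions, calls, self.PARAMS)
        assert len(segs) == 1
        assert segs[0].n_snps == 50 and segs[0].n_het_inside == 0

    def test_single_interior_het_tolerated(self):
        positions = np.arange(52) * 40_000
        calls = np.array([1] + [0] * 25 + [1] + [0] * 24 + [1], dtype=float)
        segs = detect_roh(positions, calls, self.PARAMS)
        assert len(segs) == 1 and segs[0].n_het_inside == 1

    def test_too_few_snps_gives_no_segment(self):
        positions = np.arange(20) * 100_000
        calls = np.zeros(20)
        assert detect_roh(positions, calls, self.PARAMS) == []

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            detect_roh(np.array([10, 5]), np.array([0.0, 0.0]), self.PARAMS)

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        positions = np.cumsum(rng.integers(1, 30_000, size=n))
        # occasional big gap to exercise the block splitting
        for k in rng.choice(n, size=max(1, n // 50), replace=False):
            positions[k:] += 200_000
        calls = rng.choice(
            [0.0, 1.0, 2.0, np.nan], size=n, p=[0.45, 0.10, 0.40, 0.05]
        )
        params = ROHParams(
            min_snps=int(rng.integers(3, 10)),
            max_het=int(rng.integers(0, 3)),
            max_gap_bp=100_000,
            min_length_bp=int(rng.integers(1, 200_000)),
        )
        got = segs_as_tuples(detect_roh(positions, calls, params))
        assert sorted(got) == sorted(roh_oracle(positions, calls, params))


def seg(sample, start, end, chrom="chr2"):
    return ROHSegment(sample, chrom, start, end, n_snps=50, n_het_inside=0)


class TestSharedROHRegion:
    def test_nine_of_ten_sharing(self):
        cases = [f"c{i}" for i in range(10)]
        segs = {c: [seg(c, 1000, 2000)] for c in cases[:9]}
        segs[cases[9]] = []
        shared = shared_roh_region(segs, cases, 0.9)
        assert shared == [("chr2", 1000, 2000)]

    def test_full_sharing_required_gives_empty(self):
        cases = [f"c{i}" for i in range(10)]
        segs = {c: [seg(c, 1000, 2000)] for c in cases[:9]}
        segs[cases[9]] = []
        assert shared_roh_region(segs, cases, 1.0) == []

    def test_two_case_intersection_by_sweep_line(self):
        segs = {"a": [seg("a", 100, 300)], "b": [seg("b", 200, 400)]}
        assert shared_roh_region(segs, ["a", "b"], 1.0) == [("chr2", 200, 300)]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            shared_roh_region({}, ["a"], 0.0)

    def test_coverage_conservation(self):
        rng = np.random.default_rng(5)
        cases = [f"c{i}" for i in range(8)]
        segs = {}
        for c in cases:
            n = int(rng.integers(0, 4))
            ivals = []
            for _ in range(n):
                a = int(rng.integers(0, 10_000))
                ivals.append(seg(c, a, a + int(rng.integers(100, 3000))))
            segs[c] = ivals
        frac = 0.5
        shared = shared_roh_region(segs, cases, frac)
        need = math.ceil(frac * len(cases))
        total_case_len = sum(
            s.end - s.start + 1 for c in cases for s in segs[c]
        )
        shared_len = sum(b - a + 1 for _, a, b in shared)
        assert total_case_len >= shared_len * need


class TestROHScanOnSyntheticArray:
    def test_planted_block_recovered_in_nine_cases(self, default_dataset):
        geno = rio.read_array_genotypes(default_dataset.array_genotypes)
        snp_map = rio.read_snp_map(default_dataset.array_snp_map)
        sheet = rio.read_sample_sheet(default_dataset.array_sheet)
        cases = [s for s in sheet.sample_ids if sheet.roles[s] == "case"]
        segments = roh_scan(geno, snp_map, sample_ids=cases)
        blk = default_dataset.truth["autozygous_block"]
        mid = (blk["start"] + blk["end"]) // 2
        covered = sum(
            any(s.chrom == blk["chrom"] and s.start <= mid <= s.end for s in segments[c])
            for c in cases
        )
        assert covered >= 9
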