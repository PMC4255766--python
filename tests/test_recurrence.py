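"""Region-pair rates, bin-pair scanning, hot regions, partner profiles."""

import numpy as np
import pandas as pd
import pytest

from xchange import (Cohort, GenomeModel, GenomicInterval, bin_pair_detection,
                     hot_regions, partner_profile, pooled_rate,
                     region_pair_detection)
from xchange.io import PAIR_COLUMNS, canonicalize_pairs


def make_pairs(rows):
    return canonicalize_pairs(pd.DataFrame(rows, columns=PAIR_COLUMNS[:-1]))


def cohort_of(n, groups=None):
    subjects = [f"S{i}" for i in range(n)]
    if groups is None:
        groups = ["G"] * n
    return Cohort(pd.DataFrame({"subject": subjects, "group": groups}))


REGION_A = GenomicInterval("chr1", 1000, 2000)
REGION_B = GenomicInterval("chr2", 5000, 6000)


class TestRegionPairDetection:
    def test_all_subjects_carry(self):
        rows = [[f"S{i}", "chr1", 1100, 1200, "chr2", 5100, 5200]
                for i in range(6)]
        det = region_pair_detection(make_pairs(rows),
                                    cohort_of(6, ["X"] * 3 + ["Y"] * 3),
                                    REGION_A, REGION_B)
        assert (det["rate"] == 1.0).all()

    def test_orientation_symmetric(self):
        rows = [["S0", "chr1", 1100, 1200, "chr2", 5100, 5200]]
        det_fwd = region_pair_detection(make_pairs(rows), cohort_of(1),
                                        REGION_A, REGION_B)
        det_rev = region_pair_detection(make_pairs(rows), cohort_of(1),
                                        REGION_B, REGION_A)
        assert det_fwd.iloc[-1]["carriers"] == det_rev.iloc[-1]["carriers"] == 1

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="cohort"):
            region_pair_detection(make_pairs([]), cohort_of(0), REGION_A, REGION_B)

    def test_pooled_rate_identity_published_cohort(self):
        # size-weighted mean of group rates reproduces the pooled cohort rate
        sizes = [238, 224, 340, 602, 77]
        assert pooled_rate([18.07, 20.54, 15.88, 16.61, 18.18], sizes) == \
            pytest.approx(17.35, abs=0.01)
        assert pooled_rate([53.36, 45.98, 36.76, 36.71, 35.06], sizes) == \
            pytest.approx(40.72, abs=0.01)

    def test_planted_binomial_recovery(self):
        rng = np.random.default_rng(11)
        groups = ["X"] * 100 + ["Y"] * 100
        cohort = cohort_of(200, groups)
        probs = {"X": 0.4, "Y": 0.7}
        rows = []
        carriers = {"X": 0, "Y": 0}
        for s, g in zip(cohort.subjects, groups):
            if rng.random() < probs[g]:
                carriers[g] += 1
                rows.append([s, "chr1", 1100, 1200, "chr2", 5100, 5200])
            rows.append([s, "chr3", 0, 100, "chr2", 0, 100])  # background
        det = region_pair_detection(make_pairs(rows), cohort, REGION_A, REGION_B)
        for g in ("X", "Y"):
            row = det[det["group"] == g].iloc[0]
            assert row["carriers"] == carriers[g]
            assert row["rate"] == pytest.approx(
                probs[g], abs=3 * np.sqrt(probs[g] * (1 - probs[g]) / 100))

    def test_carrier_sets_nest_when_regions_nest(self):
        rows = [["S0", "chr1", 1100, 1200, "chr2", 5100, 5200],
                ["S1", "chr1", 1500, 1600, "chr2", 5500, 5600]]
        inner = GenomicInterval("chr1", 1000, 1300)
        det_inner = region_pair_detection(make_pairs(rows), cohort_of(2),
                                          inner, REGION_B)
        det_outer = region_pair_detection(make_pairs(rows), cohort_of(2),
                                          REGION_A, REGION_B)
        assert det_inner.iloc[-1]["carriers"] <= det_outer.iloc[-1]["carriers"]


class TestBinPairDetection:
    def test_planted_top_record(self):
        rows = []
        for i in range(10):
            if i < 8:
                rows.append([f"S{i}", "chr1", 1000, 1100, "chr2", 600, 700])
            rows.append([f"S{i}", "chr3", 50_000 + 1000 * i, 50_100 + 1000 * i,
                         "chr2", 90_000 + 1000 * i, 90_100 + 1000 * i])
        records = bin_pair_detection(make_pairs(rows), cohort_of(10),
                                     bin_size=200, min_rate=0.5)
        assert records[0].bin_a == ("chr1", 5)
        assert records[0].bin_b == ("chr2", 3)
        assert records[0].detection_rate == pytest.approx(0.8)

    def test_straddling_fragment_counts_once_per_bin_pair(self):
        # fragment a straddles bins 5 and 6: subject carried in both pairs, once each
        rows = [["S0", "chr1", 1150, 1250, "chr2", 600, 700]]
        records = bin_pair_detection(make_pairs(rows), cohort_of(1),
                                     bin_size=200, min_rate=0.0)
        keys = {(r.bin_a, r.bin_b) for r in records}
        assert (("chr1", 5), ("chr2", 3)) in keys
        assert (("chr1", 6), ("chr2", 3)) in keys
        assert all(len(r.carriers) == 1 for r in records)

    def test_same_bin_self_pairs_excluded(self):
        rows = [["S0", "chr1", 1000, 1050, "chr1", 1100, 1150]]
        records = bin_pair_detection(make_pairs(rows), cohort_of(1),
                                     bin_size=200, min_rate=0.0)
        assert records == []

    def test_huge_bins_degenerate_to_chromosome_pairs(self, rng, toy_genome):
        from conftest import random_pairs
        pairs = random_pairs(rng, toy_genome, n=60)
        cohort = cohort_of(5)
        pairs["subject"] = [f"S{i % 5}" for i in range(len(pairs))]
        records = bin_pair_detection(pairs, cohort, bin_size=10**9,
                                     min_rate=0.0, genome=toy_genome)
        expected = {}
        for r in pairs.itertuples(index=False):
            if r.chrom_a != r.chrom_b:
                expected.setdefault((r.chrom_a, r.chrom_b), set()).add(r.subject)
        got = {(r.bin_a[0], r.bin_b[0]): set(r.carriers) for r in records}
        assert got == expected

    def test_rate_threshold_monotone(self, rng, toy_genome):
        from conftest import random_pairs
        pairs = random_pairs(rng, toy_genome, n=80)
        cohort = cohort_of(5)
        pairs["subject"] = [f"S{i % 5}" for i in range(len(pairs))]
        low = bin_pair_detection(pairs, cohort, 200, min_rate=0.0)
        high = bin_pair_detection(pairs, cohort, 200, min_rate=0.4)
        assert len(high) <= len(low)
        assert {(r.bin_a, r.bin_b) for r in high} <= \
            {(r.bin_a, r.bin_b) for r in low}


def stack(chrom, start, end, n, subject="S0", partner=("chr9", 10_000)):
    """n identical pairs with fragment a stacked on [start, end)."""
    pc, ps = partner
    return [[f"{subject}_{i}", chrom, start, end, pc, ps + 200 * i,
             ps + 200 * i + 100] for i in range(n)]


class TestHotRegions:
    def test_planted_stack_with_background(self):
        rows = stack("chr1", 1000, 1100, 1200)
        for i in range(50):  # scattered background, far from the stack
            rows.append([f"B{i}", "chr1", 50_000 + 500 * i, 50_000 + 500 * i + 100,
                         "chr2", 1000 * i, 1000 * i + 100])
        regions = hot_regions(make_pairs(rows), min_occurrence=1000)
        assert len(regions) == 1
        assert regions[0].occurrence == 1200
        assert (regions[0].interval.start, regions[0].interval.end) == (1000, 1100)

    def test_threshold_strictly_greater(self):
        rows = stack("chr1", 1000, 1100, 999)
        assert hot_regions(make_pairs(rows), min_occurrence=1000) == []
        rows = stack("chr1", 1000, 1100, 1001)
        assert len(hot_regions(make_pairs(rows), min_occurrence=1000)) == 1

    def test_merge_gap_controls_linkage(self):
        rows = stack("chr1", 1000, 1100, 1200) + \
            stack("chr1", 1250, 1350, 1200, subject="T0")
        near = hot_regions(make_pairs(rows), min_occurrence=1000, merge_gap=0)
        assert len([r for r in near if r.interval.chrom == "chr1"]) == 2
        merged = hot_regions(make_pairs(rows), min_occurrence=1000, merge_gap=200)
        chr1_regions = [r for r in merged if r.interval.chrom == "chr1"]
        assert len(chr1_regions) == 1
        assert (chr1_regions[0].interval.start, chr1_regions[0].interval.end) == \
            (1000, 1350)

    def test_occurrence_bounded_by_fragments(self):
        rows = stack("chr1", 1000, 1100, 1500)
        regions = hot_regions(make_pairs(rows), min_occurrence=1000)
        assert sum(r.occurrence for r in regions) <= 2 * len(rows)


class TestPartnerProfile:
    def test_all_partners_one_bin(self):
        rows = stack("chr1", 1000, 1100, 30, partner=("chr2", 5_000))
        pairs = make_pairs(rows)
        prof = partner_profile(GenomicInterval("chr1", 1000, 1100), pairs)
        assert prof["top_partner_share"] == 1.0
        assert prof["top_partner_bin"] == ("chr2", 0)

    def test_uniform_partners_share_near_inverse_k(self):
        rng = np.random.default_rng(3)
        rows = []
        k = 10
        for i in range(600):
            b = int(rng.integers(k))
            rows.append([f"S{i}", "chr1", 1000, 1100,
                         "chr2", b * 1_000_000 + 500, b * 1_000_000 + 600])
        prof = partner_profile(GenomicInterval("chr1", 1000, 1100),
                               make_pairs(rows))
        assert prof["top_partner_share"] == pytest.approx(1 / k, abs=0.06)

    def test_no_pairs_errors(self):
        rows = stack("chr1", 1000, 1100, 3)
        with pytest.raises(ValueError, match="no pairs"):
            partner_profile(GenomicInterval("chr3", 0, 100), make_pairs(rows))

    def test_planted_reciprocal_link_dominates(self, small_sim):
        from xchange import run_filters
        pairs, _ = run_filters(small_sim.pairs.drop(columns="provenance"),
                               small_sim.repeats, small_sim.lowmap)
        hot2 = small_sim.ground_truth.hot_regions[1]
        region = GenomicInterval(hot2["chrom"], hot2["start"], hot2["end"])
        prof = partner_profile(region, pairs)
        pchrom, pstart, _ = hot2["partner"]
        assert prof["top_partner_bin"] == (pchrom, pstart // 1_000_000)
        assert prof["top_partner_share"] > 0.9
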