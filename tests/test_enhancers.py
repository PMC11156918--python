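"""Enhancer calling: consensus/candidate filtering oracles, the fold-change +
floor rule, tissue classification, marker-gene thresholds, and summaries."""

import numpy as np
import pandas as pd
import pytest

from chondroscape.enhancers import (
    CHONDROGENIC,
    NON_CHONDROGENIC,
    CallingParams,
    call_differential,
    candidate_regions,
    classify_genes,
    classify_tissue,
    consensus_atac,
    pct,
    summarize_landscape,
)
from chondroscape.formats import CoverageTrack
from chondroscape.intervals import ChromSizes, GenomicInterval

from conftest import random_intervals


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 100_000})


class TestConsensusAtac:
    def test_reciprocal_overlap_union_extended(self, sizes):
        got = consensus_atac([iv("chr1", 1000, 1300)], [iv("chr1", 1250, 1400)],
                             sizes)
        assert got == [iv("chr1", 850, 1550)]

    def test_non_reproducible_peaks_dropped(self, sizes):
        got = consensus_atac([iv("chr1", 1000, 1300)], [iv("chr1", 2000, 2100)],
                             sizes)
        assert got == []

    def test_identical_replicates_reduce_to_extension(self, sizes):
        peaks = [iv("chr1", 1000, 1300), iv("chr1", 5000, 5200)]
        got = consensus_atac(peaks, list(peaks), sizes)
        assert [(g.start, g.end) for g in got] == [(850, 1450), (4850, 5350)]

    def test_empty_replicate_warns(self, sizes):
        with pytest.warns(UserWarning):
            assert consensus_atac([], [iv("chr1", 0, 100)], sizes) == []


class TestCandidateRegions:
    def test_kept_dropped_rules(self):
        peaks = [iv("chr1", 1000, 1500), iv("chr1", 3000, 3500)]
        consensus = [iv("chr1", 900, 4000)]
        promoters = [iv("chr1", 3499, 3600)]  # 1 bp overlap with second peak
        got = candidate_regions(peaks, consensus, promoters)
        assert got == [iv("chr1", 1000, 1500)]

    def test_oracle_brute_force_set_difference(self, rng):
        for _ in range(50):
            peaks = random_intervals(rng, 10)
            consensus = random_intervals(rng, 6)
            promoters = random_intervals(rng, 4)
            got = {p.key() for p in candidate_regions(peaks, consensus, promoters)}
            expected = set()
            for p in peaks:
                in_cons = any(p.overlap_len(c) >= 1 for c in consensus)
                in_prom = any(p.overlap_len(w) >= 1 for w in promoters)
                if in_cons and not in_prom:
                    expected.add(p.key())
            assert got == expected


class TestCallDifferential:
    def call_one(self, cov_pos, cov_neg):
        return call_differential([iv("chr1", 100, 400)], [cov_pos], [cov_neg])

    def test_chondrogenic_rule(self):
        (call,) = self.call_one(2.0, 0.4)
        assert call.activity == CHONDROGENIC
        assert call.fold_change == pytest.approx(5.0)

    def test_floor_blocks_low_coverage(self):
        assert self.call_one(0.4, 0.05) == []

    def test_mirrored_rule(self):
        (call,) = self.call_one(0.1, 2.0)
        assert call.activity == NON_CHONDROGENIC
        assert call.fold_change == pytest.approx(20.0)

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError):
            self.call_one(-0.1, 1.0)

    def test_merge_within_gap_recomputes_fold_change(self):
        candidates = [iv("chr1", 100, 400), iv("chr1", 800, 1000)]
        calls = call_differential(candidates, [2.0, 4.0], [0.4, 0.2])
        assert len(calls) == 1
        (c,) = calls
        assert (c.interval.start, c.interval.end) == (100, 1000)
        assert c.cov_pos == 4.0 and c.cov_neg == 0.4
        assert c.fold_change == pytest.approx(10.0)

    def test_classes_merged_separately_and_exclusive(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 20))
            cands = sorted(random_intervals(rng, n, chroms=("chr1",)),
                           key=lambda v: v.key())
            cov_pos = rng.uniform(0, 3, n)
            cov_neg = rng.uniform(0, 3, n)
            calls = call_differential(cands, cov_pos, cov_neg)
            chondro = [c.interval for c in calls if c.activity == CHONDROGENIC]
            non = [c.interval for c in calls if c.activity == NON_CHONDROGENIC]
            # no candidate satisfies both rules at once
            for cp, cn in zip(cov_pos, cov_neg):
                both = (
                    cp >= 0.5 and cp / max(cn, 0.01) >= 4
                    and cn >= 0.5 and cn / max(cp, 0.01) >= 4
                )
                assert not both

    def test_raising_threshold_never_adds_calls(self, rng):
        n = 40
        cands = [iv("chr1", 1000 * i + 100, 1000 * i + 400) for i in range(n)]
        cov_pos = rng.uniform(0, 4, n)
        cov_neg = rng.uniform(0, 2, n)
        previous = None
        for fc in (2.0, 4.0, 6.0, 10.0):
            params = CallingParams(fc_threshold=fc)
            n_calls = len(call_differential(cands, cov_pos, cov_neg, params))
            if previous is not None:
                assert n_calls <= previous
            previous = n_calls


def make_track(sizes, regions_values):
    starts = np.array([r.start for r, _ in regions_values])
    ends = np.array([r.end for r, _ in regions_values])
    values = np.array([v for _, v in regions_values], dtype=float)
    order = np.argsort(starts)
    return CoverageTrack(
        sizes, {"chr1": (starts[order], ends[order], values[order])}
    )


class TestClassifyTissue:
    @pytest.mark.parametrize(
        "limb_cov,trunk_cov,expected",
        [
            (1.0, 0.4, "limb_enriched"),   # 2.5x
            (1.0, 0.6, "pan"),             # 1.67x
            (0.0, 0.6, "trunk_enriched"),  # 0.6 / pseudocount 0.01 = 60x
        ],
    )
    def test_two_fold_rule_with_pseudocount(self, sizes, limb_cov, trunk_cov,
                                            expected):
        region = iv("chr1", 100, 400)
        call = call_differential([region], [2.0], [0.1])[0]
        limb_track = make_track(sizes, [(region, limb_cov)])
        trunk_track = make_track(sizes, [(region, trunk_cov)])
        (agg,) = classify_tissue([call], [], limb_track, trunk_track)
        assert agg.tissue_class == expected

    def test_overlapping_calls_aggregate(self, sizes):
        a = call_differential([iv("chr1", 100, 400)], [2.0], [0.1], tissue="limb")[0]
        b = call_differential([iv("chr1", 300, 600)], [2.0], [0.1], tissue="trunk")[0]
        track = make_track(sizes, [(iv("chr1", 100, 600), 1.0)])
        agg = classify_tissue([a], [b], track, track)
        assert len(agg) == 1
        assert (agg[0].interval.start, agg[0].interval.end) == (100, 600)
        assert agg[0].tissue_class == "pan"


class TestClassifyGenes:
    def de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2FC", "padj"])

    def test_shared_limb_specific_and_boundary(self):
        tables = {
            "limb": self.de([("a", 2.0, 0.01), ("b", 2.0, 0.01), ("c", 1.5, 0.01)]),
            "trunk": self.de([("a", 1.9, 0.04), ("b", 0.3, 0.9), ("c", 0.0, 0.9)]),
        }
        out = {g.gene: g for g in classify_genes(tables)}
        assert out["a"].tissue_class == "shared"
        assert out["b"].tissue_class == "limb_specific"
        # log2FC exactly at the threshold is NOT a marker (strict inequality)
        assert not out["c"].is_chondrogenic

    def test_neg_markers_and_missing_genes_flagged(self):
        tables = {
            "limb": self.de([("a", -2.0, 0.01), ("d", 2.0, 0.01)]),
            "trunk": self.de([("a", -2.2, 0.001)]),
        }
        out = {g.gene: g for g in classify_genes(tables)}
        assert out["a"].marker_class == {"limb": "egfp_neg_marker",
                                        "trunk": "egfp_neg_marker"}
        assert out["a"].tissue_class is None
        assert out["d"].missing_in == ("trunk",)
        assert out["d"].tissue_class == "limb_specific"


class TestSummaries:
    def test_percentage_rounding_matches_printed_precision(self):
        assert pct(2003, 2704) == 74
        assert pct(483, 2704) == 18
        assert pct(218, 2704) == 8
        assert pct(2704, 3583) == 75
        assert pct(1, 1) == 100
        assert pct(73, 2704, decimals=1) == 2.7
        assert pct(5, 879, decimals=1) == 0.6

    def test_landscape_partition(self, sizes):
        calls = [
            call_differential([iv("chr1", 1000 * i + 100, 1000 * i + 400)],
                              [2.0], [0.1])[0]
            for i in range(3)
        ]
        track = make_track(sizes, [(c.interval, 1.0) for c in calls])
        agg = classify_tissue(calls, [], track, track)
        summary = summarize_landscape(agg, non_chondro=[])
        counts = summary["tissue_class_counts"]
        assert sum(counts.values()) == summary["n_chondrogenic"] == 3
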