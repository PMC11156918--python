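"""Height-variance attribution: coding split, size matching, and the
cumulative curve against a prefix-sum oracle."""

import numpy as np
import pytest

from chondroscape.enhancers import AggregatedEnhancer
from chondroscape.heightvar import (
    GWSLocus,
    VarianceCurve,
    compare_sets,
    cumulative_curve,
    split_coding,
    top_k_enhancers,
)
from chondroscape.intervals import (
    ChromSizes,
    GeneRecord,
    GenomicInterval,
    ParameterError,
)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def locus(chrom, start, end, v):
    return GWSLocus(iv(chrom, start, end), v)


def agg(interval, fc_limb, fc_trunk=1.0):
    return AggregatedEnhancer(interval, 1.0, 1.0, "pan", fc_limb, fc_trunk,
                              fc_limb - 1.0, fc_trunk - 1.0)


class TestSplitCoding:
    def test_gene_desert_vs_genic(self):
        genes = [GeneRecord(GenomicInterval("chr1", 100, 500, "+"), "g")]
        coding, non = split_coding(
            [locus("chr1", 0, 1000, 0.1), locus("chr1", 5000, 6000, 0.2)], genes
        )
        assert [l.interval.start for l in coding] == [0]
        assert [l.interval.start for l in non] == [5000]
        assert coding[0].coding is True and non[0].coding is False

    def test_matches_double_loop_oracle(self, rng):
        genes = [
            GeneRecord(GenomicInterval("chr1", int(s), int(s) + 200, "+"), f"g{i}")
            for i, s in enumerate(rng.integers(0, 9000, size=6))
        ]
        loci = [
            locus("chr1", int(s), int(s) + 300, float(rng.uniform(0, 1)))
            for s in range(0, 10000, 1000)
        ]
        coding, non = split_coding(loci, genes)
        expected_coding = {
            l.interval.key() for l in loci
            if any(l.interval.overlap_len(g.interval) >= 1 for g in genes)
        }
        assert {l.interval.key() for l in coding} == expected_coding
        assert len(coding) + len(non) == len(loci)


class TestTopK:
    def setup_method(self):
        self.sizes = ChromSizes({"chr1": 100_000, "chrX": 100_000})

    def test_rank_by_max_fold_change(self):
        calls = [
            agg(iv("chr1", 0, 100), 10.0),
            agg(iv("chr1", 1000, 1100), 6.0),
            agg(iv("chr1", 2000, 2100), 8.0),
        ]
        top = top_k_enhancers(calls, k=2, sizes=self.sizes)
        assert [t.max_fold_change for t in top] == [10.0, 8.0]

    def test_sex_chromosome_excluded(self):
        calls = [agg(iv("chrX", 0, 100), 99.0), agg(iv("chr1", 0, 100), 2.0)]
        top = top_k_enhancers(calls, k=1, sizes=self.sizes)
        assert top[0].interval.chrom == "chr1"

    def test_k_larger_than_pool_returns_all_with_flag(self):
        calls = [agg(iv("chr1", 0, 100), 5.0)]
        with pytest.warns(UserWarning):
            assert top_k_enhancers(calls, k=877, sizes=self.sizes) == calls

    def test_coverage_diff_metric_switch(self):
        calls = [
            agg(iv("chr1", 0, 100), fc_limb=100.0),
            AggregatedEnhancer(iv("chr1", 1000, 1100), 1.0, 1.0, "pan",
                               2.0, 1.0, 500.0, 1.0),
        ]
        top = top_k_enhancers(calls, k=1, sizes=self.sizes, metric="coverage_diff")
        assert top[0].interval.start == 1000


class TestCumulativeCurve:
    def test_definition_example(self):
        loci = [
            locus("chr1", 0, 100, 0.5),
            locus("chr1", 1000, 1100, 0.3),
            locus("chr1", 2000, 2100, 0.2),
        ]
        enh = [iv("chr1", 50, 60), iv("chr1", 2050, 2060)]  # overlap 1st, 3rd
        curve, totals = cumulative_curve(loci, enh)
        np.testing.assert_allclose(curve.x, [0.5, 0.8, 1.0])
        np.testing.assert_allclose(curve.y, [0.5, 0.5, 0.7])
        assert totals["n_overlapped"] == 2
        assert totals["y_total"] == pytest.approx(0.7)

    def test_no_enhancers_gives_zero_curve(self):
        loci = [locus("chr1", 0, 100, 0.5)]
        curve, totals = cumulative_curve(loci, [])
        np.testing.assert_allclose(curve.y, [0.0])
        assert totals["fraction_of_variance"] == 0.0

    def test_overlapping_loci_rejected(self):
        with pytest.raises(ParameterError):
            cumulative_curve(
                [locus("chr1", 0, 100, 0.1), locus("chr1", 50, 150, 0.1)], []
            )

    def test_oracle_prefix_sums(self, rng):
        """Curve equals a non-iterative vectorized prefix-sum oracle on
        random loci/enhancers, and the final y is order-independent."""
        for _ in range(100):
            n = 30
            starts = np.arange(n) * 1000 + rng.integers(0, 200, size=n)
            loci = [
                locus("chr1", int(s), int(s) + 300, float(rng.pareto(1.5) + 0.01))
                for s in starts
            ]
            enh = [
                iv("chr1", int(s), int(s) + 50)
                for s in rng.integers(0, n * 1000, size=10)
            ]
            curve, totals = cumulative_curve(loci, enh)
            order = sorted(
                range(n),
                key=lambda i: (-loci[i].variance_explained, loci[i].interval.key()),
            )
            v = np.array([loci[i].variance_explained for i in order])
            flags = np.array([
                any(loci[i].interval.overlap_len(e) >= 1 for e in enh)
                for i in order
            ])
            np.testing.assert_allclose(curve.x, np.cumsum(v))
            np.testing.assert_allclose(curve.y, np.cumsum(v * flags))
            assert totals["y_total"] == pytest.approx(float(v[flags].sum()))
            # structural invariants
            assert (np.diff(curve.y) >= 0).all()
            assert (curve.y <= curve.x + 1e-12).all()

    def test_adding_enhancers_never_lowers_curve(self, rng):
        n = 20
        loci = [locus("chr1", i * 1000, i * 1000 + 300, float(rng.uniform(0, 1)))
                for i in range(n)]
        enh = [iv("chr1", int(s), int(s) + 50)
               for s in rng.integers(0, n * 1000, size=8)]
        small, _ = cumulative_curve(loci, enh[:4])
        large, _ = cumulative_curve(loci, enh)
        assert (large.y >= small.y - 1e-12).all()

    def test_null_placement_fraction_matches_hit_rate(self, rng):
        """With enhancer placement independent of variance, the variance
        fraction explained matches the fraction of loci overlapped within
        Monte-Carlo error."""
        n = 400
        loci = [locus("chr1", i * 1000, i * 1000 + 500, float(rng.uniform(0.5, 1.5)))
                for i in range(n)]
        hit = rng.random(n) < 0.3
        enh = [iv("chr1", i * 1000 + 100, i * 1000 + 150)
               for i in range(n) if hit[i]]
        _, totals = cumulative_curve(loci, enh)
        assert totals["fraction_of_variance"] == pytest.approx(
            hit.mean(), abs=0.08
        )


class TestCompareSets:
    def test_superset_monotone_and_identical_rows(self):
        loci = [locus("chr1", i * 1000, i * 1000 + 300, 0.1 * (i + 1))
                for i in range(10)]
        small = [iv("chr1", 100, 150)]
        big = small + [iv("chr1", 5100, 5150)]
        table = compare_sets(loci, {"small": small, "big": big, "small2": small})
        assert table.loc["big", "y_total"] >= table.loc["small", "y_total"]
        assert table.loc["small"].equals(table.loc["small2"])


class TestVarianceCurveInvariants:
    def test_rejects_decreasing_or_excess_y(self):
        with pytest.raises(ParameterError):
            VarianceCurve([0.1, 0.2], [0.2, 0.1])
        with pytest.raises(ParameterError):
            VarianceCurve([0.1, 0.2], [0.15, 0.25])
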