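"""Motif scanning: exact threshold calibration vs exhaustive enumeration,
strand symmetry, naive-scan hit oracle, and enrichment arithmetic."""

import numpy as np
import pytest

from chondroscape.intervals import ChromSizes, GenomicInterval, ParameterError
from chondroscape.motifs import (
    PositionCountMatrix,
    calibrate_threshold,
    center_regions,
    count_hits,
    enrich_all,
    enrichment,
    log_odds_matrix,
    read_pcms,
    reverse_complement,
    write_pcms,
)

BASES = "ACGT"


def consensus_pcm(consensus, name="toy", strong=94.0, weak=2.0):
    counts = np.full((4, len(consensus)), weak)
    for j, base in enumerate(consensus):
        counts[BASES.index(base), j] = strong
    return PositionCountMatrix(name, counts)


class TestPcm:
    def test_invariants(self):
        with pytest.raises(ParameterError):
            PositionCountMatrix("short", np.ones((4, 3)))
        with pytest.raises(ParameterError):
            PositionCountMatrix("neg", -np.ones((4, 5)))

    def test_io_round_trip(self, tmp_path):
        pcms = [consensus_pcm("ACGTAC", "m1"), consensus_pcm("TTTTGG", "m2")]
        p = tmp_path / "m.pcm"
        write_pcms(pcms, p)
        back = read_pcms(p)
        assert [m.name for m in back] == ["m1", "m2"]
        np.testing.assert_allclose(back[0].counts, pcms[0].counts)


class TestCenterRegions:
    def test_symmetric_trim_and_growth(self):
        (a,) = center_regions([GenomicInterval("chr1", 1000, 1600)], 500)
        assert (a.start, a.end) == (1050, 1550)
        (b,) = center_regions([GenomicInterval("chr1", 1000, 1100)], 500)
        assert (b.start, b.end) == (800, 1300)

    def test_clipping_flagged(self):
        sizes = ChromSizes({"chr1": 300}, autosomes=["chr1"])
        with pytest.warns(UserWarning):
            (w,) = center_regions([GenomicInterval("chr1", 80, 120)], 500, sizes)
        assert (w.start, w.end) == (0, 300)


class TestCalibration:
    def test_uniform_pcm_is_degenerate(self):
        pcm = PositionCountMatrix("flat", np.full((4, 6), 10.0))
        t = calibrate_threshold(pcm, alpha=0.001)
        hits, positions = count_hits(["ACGTACGTACGT"], pcm, t)
        assert hits == 0 and positions > 0

    def test_alpha_one_hits_everything(self):
        pcm = consensus_pcm("ACGTA")
        t = calibrate_threshold(pcm, alpha=1.0)
        hits, positions = count_hits(["ACGTACGTAC"], pcm, t)
        assert hits == positions

    def test_threshold_matches_exhaustive_enumeration(self):
        """For a length-4 motif the convolution-based tail equals brute-force
        enumeration over all 256 4-mers on the same score lattice."""
        pcm = consensus_pcm("ACGT", strong=20.0, weak=3.0)
        grid = 0.01
        lom_grid = np.round(log_odds_matrix(pcm) / grid).astype(int)
        scores = sorted(
            sum(lom_grid[ { "A":0,"C":1,"G":2,"T":3 }[b], j]
                for j, b in enumerate(kmer))
            for kmer in (
                a + b + c + d
                for a in BASES for b in BASES for c in BASES for d in BASES
            )
        )
        scores = np.array(scores)
        for alpha in (0.5, 0.05, 0.004):
            t = calibrate_threshold(pcm, alpha=alpha, grid=grid)
            t_idx = int(np.ceil(t / grid - 1e-9))
            # tail at returned threshold obeys the bound...
            assert (scores >= t_idx).mean() <= alpha
            # ...and the threshold is minimal on the lattice
            assert (scores >= t_idx - 1).mean() > alpha

    def test_alpha_validation(self):
        with pytest.raises(ParameterError):
            calibrate_threshold(consensus_pcm("ACGTA"), alpha=0.0)


class TestCountHits:
    def test_consensus_and_reverse_complement_hit(self):
        pcm = consensus_pcm("CATTGTTC")
        t = calibrate_threshold(pcm, alpha=0.001)
        pad = "AAAAAGAAAA"
        hits_fwd, _ = count_hits([pad + "CATTGTTC" + pad], pcm, t)
        hits_rev, _ = count_hits([pad + reverse_complement("CATTGTTC") + pad],
                                 pcm, t)
        assert hits_fwd >= 1
        assert hits_rev == hits_fwd

    def test_n_windows_excluded_from_positions(self):
        pcm = consensus_pcm("ACGTA")
        t = calibrate_threshold(pcm, alpha=0.5)
        _, clean = count_hits(["ACGTACGTAC"], pcm, t)
        _, with_n = count_hits(["ACGTNCGTAC"], pcm, t)
        assert clean == 2 * (10 - 5 + 1)
        assert with_n == clean - 2 * 5  # N kills 5 windows per strand

    def test_short_sequence_contributes_nothing(self):
        pcm = consensus_pcm("ACGTA")
        assert count_hits(["ACG"], pcm, 0.0) == (0, 0)

    def test_oracle_naive_scan(self, rng):
        """Hit counts equal an independent character-by-character scanner on
        random sequences with planted consensus occurrences."""
        pcm = consensus_pcm("CATTGTTC")
        t = calibrate_threshold(pcm, alpha=0.001)
        grid = 0.01
        lom_grid = np.round(log_odds_matrix(pcm) / grid).astype(int)
        t_idx = int(np.ceil(t / grid - 1e-9))
        idx = {b: i for i, b in enumerate(BASES)}
        for _ in range(100):
            seq = "".join(BASES[i] for i in rng.integers(0, 4, size=120))
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(0, len(seq) - 8))
                seq = seq[:pos] + "CATTGTTC" + seq[pos + 8:]
            expected = 0
            for strand in (seq, reverse_complement(seq)):
                for i in range(len(strand) - 8 + 1):
                    window = strand[i:i + 8]
                    score = sum(lom_grid[idx[b], j] for j, b in enumerate(window))
                    if score >= t_idx:
                        expected += 1
            hits, _ = count_hits([seq], pcm, t)
            assert hits == expected

    def test_reverse_complementing_inputs_is_invariant(self, rng):
        pcm = consensus_pcm("CATTGTTC")
        t = calibrate_threshold(pcm, alpha=0.01)
        seqs = ["".join(BASES[i] for i in rng.integers(0, 4, size=200))
                for _ in range(5)]
        assert count_hits(seqs, pcm, t) == count_hits(
            [reverse_complement(s) for s in seqs], pcm, t
        )

    def test_raising_threshold_never_adds_hits(self, rng):
        pcm = consensus_pcm("CATTGTTC", strong=30, weak=10)
        seqs = ["".join(BASES[i] for i in rng.integers(0, 4, size=300))]
        previous = None
        for t in np.linspace(-5, 10, 12):
            hits, _ = count_hits(seqs, pcm, float(t))
            if previous is not None:
                assert hits <= previous
            previous = hits


class TestEnrichment:
    def test_equal_rates_zero(self):
        assert enrichment("m", 10, 1000, 10, 1000).log2_fold_change == 0.0

    def test_four_fold_rate_in_large_count_limit(self):
        e = enrichment("m", 40_000, 1_000_000, 10_000, 1_000_000)
        assert e.log2_fold_change == pytest.approx(2.0, abs=1e-3)

    def test_zero_hits_both_sides_is_zero(self):
        assert enrichment("m", 0, 1000, 0, 1000).log2_fold_change == 0.0

    def test_zero_positions_rejected(self):
        with pytest.raises(ParameterError):
            enrichment("m", 0, 0, 1, 10)


class TestPlantedRanking:
    def test_planted_motif_ranks_top3_of_decoys(self, rng):
        """Target sequences with 5x planted motif density rank the motif in
        the top 3 of 20 decoys by log2 fold change (seed-fixed)."""
        real = consensus_pcm("CATTGTTC", "REAL")
        decoys = []
        for d in range(20):
            cons = "".join(BASES[i] for i in rng.integers(0, 4, size=8))
            decoys.append(consensus_pcm(cons, f"DECOY_{d:02d}"))

        def make_seqs(n, rate):
            seqs = []
            for _ in range(n):
                seq = list(BASES[i] for i in rng.integers(0, 4, size=400))
                for _ in range(rng.poisson(rate)):
                    pos = int(rng.integers(0, 400 - 8))
                    seq[pos:pos + 8] = list("CATTGTTC")
                seqs.append("".join(seq))
            return seqs

        target = make_seqs(40, 1.0)
        background = make_seqs(40, 0.2)
        table = enrich_all(target, background, [real] + decoys)
        rank = table.index[table["motif"] == "REAL"][0]
        assert rank < 3
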