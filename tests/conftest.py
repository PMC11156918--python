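"""Shared fixtures: synthetic bundles and small interval/track helpers."""

import dataclasses

import numpy as np
import pytest

from chondroscape import synth as sy
from chondroscape.formats import CoverageTrack
from chondroscape.intervals import ChromSizes, GenomicInterval


@pytest.fixture(scope="session")
def bundle_zero(tmp_path_factory):
    """Seed-42 bundle with zero coverage noise and zero replicate jitter."""
    config = dataclasses.replace(sy.SynthConfig(), noise_cv=0.0, jitter=0)
    return sy.generate(config, tmp_path_factory.mktemp("bundle_zero"))


@pytest.fixture(scope="session")
def bundle_noisy(tmp_path_factory):
    """Seed-42 bundle at the default study conditions (CV 0.1, +/-50 bp)."""
    return sy.generate(sy.SynthConfig(), tmp_path_factory.mktemp("bundle_noisy"))


@pytest.fixture
def sizes10k():
    return ChromSizes({"chr1": 10_000, "chr2": 10_000})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=9_000,
                     max_len=400):
    """Small random interval sets for oracle-equivalence checks."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def step_track(rng, sizes, n_segments=15):
    """Random non-overlapping step track on chr1 for quantify oracles."""
    bounds = np.sort(rng.choice(np.arange(1, sizes["chr1"]), size=2 * n_segments,
                                replace=False))
    starts, ends, values = [], [], []
    for i in range(n_segments):
        starts.append(int(bounds[2 * i]))
        ends.append(int(bounds[2 * i + 1]))
        values.append(float(rng.uniform(0, 5)))
    segs = {
        "chr1": (np.array(starts), np.array(ends), np.array(values)),
    }
    return CoverageTrack(sizes, segs, "random")


def per_base_array(track, chrom, length):
    """Materialize a track as a dense per-base vector (oracle helper)."""
    arr = np.zeros(length)
    if chrom in track.segments:
        starts, ends, values = track.segments[chrom]
        for s, e, v in zip(starts, ends, values):
            arr[s:e] += v
    return arr
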