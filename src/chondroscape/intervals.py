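"""Genomic interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention). Inputs in 1-based
conventions are converted at the I/O boundary, never here. Interval sets are
plain Python lists of :class:`GenomicInterval`; the operations below are the
only interval arithmetic the pipeline performs, so their semantics (gap-based
merging, any-overlap tests, strand-aware promoter windows) are defined once
and reused everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "CoordinateError",
    "ParameterError",
    "GenomicInterval",
    "ChromSizes",
    "GeneRecord",
    "sort_intervals",
    "merge_within",
    "overlaps_any",
    "overlap_counts",
    "extend",
    "promoter_windows",
    "total_covered",
]


class CoordinateError(ValueError):
    """An interval lies outside its chromosome or is malformed."""


class ParameterError(ValueError):
    """An operation parameter is out of its valid range."""


_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic range ``[start, end)`` with optional score.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive; ``end > start``
    always holds, so every interval covers at least one base.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"negative start: {self!r}")
        if self.end <= self.start:
            raise CoordinateError(f"empty or inverted interval: {self!r}")
        if self.strand not in _STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length map with an autosome flag per chromosome.

    The autosome flag defaults to a name heuristic (``chrX``/``chrY``/``chrM``
    and unprefixed spellings are non-autosomal) but can be given explicitly.
    Chromosome-name dialects ("chr1" vs "1") are normalized to the spelling
    used here via :meth:`normalize`.
    """

    _NON_AUTOSOME = frozenset({"X", "Y", "M", "MT", "W", "Z"})

    def __init__(
        self,
        sizes: Mapping[str, int],
        autosomes: Iterable[str] | None = None,
    ) -> None:
        self._sizes: dict[str, int] = {}
        for name, length in sizes.items():
            if length <= 0:
                raise CoordinateError(f"non-positive length for {name}: {length}")
            self._sizes[str(name)] = int(length)
        if autosomes is None:
            self._autosomes = {
                name
                for name in self._sizes
                if name.removeprefix("chr").upper() not in self._NON_AUTOSOME
            }
        else:
            self._autosomes = set(autosomes) & set(self._sizes)

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self._autosomes

    def normalize(self, name: str) -> str:
        """Map a chromosome-name dialect onto the spelling stored here."""
        name = str(name)
        if name in self._sizes:
            return name
        alt = name.removeprefix("chr") if name.startswith("chr") else "chr" + name
        if alt in self._sizes:
            return alt
        raise CoordinateError(f"unknown chromosome {name!r}")

    def validate(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self._sizes:
            raise CoordinateError(f"unknown chromosome in {interval!r}")
        if interval.end > self._sizes[interval.chrom]:
            raise CoordinateError(
                f"{interval!r} exceeds chromosome length "
                f"{self._sizes[interval.chrom]}"
            )

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        length = self._sizes[chrom]
        return max(0, start), min(length, end)


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with its transcription start site and biotype."""

    interval: GenomicInterval
    name: str
    biotype: str = "protein_coding"

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"

    @property
    def tss(self) -> int:
        """0-based TSS position: ``start`` on +, ``end - 1`` on −."""
        if self.interval.strand == "+":
            return self.interval.start
        if self.interval.strand == "-":
            return self.interval.end - 1
        raise CoordinateError(f"gene {self.name!r} has no orientation")


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=GenomicInterval.key)


def _validate_all(
    intervals: Iterable[GenomicInterval], sizes: ChromSizes | None
) -> None:
    if sizes is not None:
        for iv in intervals:
            sizes.validate(iv)


def merge_within(
    intervals: Sequence[GenomicInterval],
    max_gap: int,
    sizes: ChromSizes | None = None,
) -> list[GenomicInterval]:
    """Merge intervals whose gap is at most ``max_gap`` bases.

    Merging is transitive: the result is the partition of the input under the
    closure of the pairwise relation ``same chrom and start − end ≤ max_gap``.
    ``max_gap = 0`` merges book-ended and overlapping intervals. Merged
    intervals are unstranded; their score is the max over member scores.
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be >= 0, got {max_gap}")
    _validate_all(intervals, sizes)
    ordered = sort_intervals(intervals)
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if (
            merged
            and iv.chrom == merged[-1].chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            prev = merged[-1]
            scores = [s for s in (prev.score, iv.score) if s is not None]
            merged[-1] = GenomicInterval(
                prev.chrom,
                prev.start,
                max(prev.end, iv.end),
                ".",
                max(scores) if scores else None,
            )
        else:
            merged.append(replace(iv, strand=".", score=iv.score))
    return merged


def _by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, list[list[int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, [[], []])
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
    return {
        chrom: (np.asarray(starts), np.asarray(ends))
        for chrom, (starts, ends) in out.items()
    }


def overlap_counts(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> np.ndarray:
    """Per-query count of subject intervals sharing >= ``min_overlap`` bases."""
    if min_overlap < 1:
        raise ParameterError(f"min_overlap must be >= 1, got {min_overlap}")
    subj = _by_chrom(subject)
    counts = np.zeros(len(query), dtype=int)
    for i, q in enumerate(query):
        if q.chrom not in subj:
            continue
        starts, ends = subj[q.chrom]
        ov = np.minimum(ends, q.end) - np.maximum(starts, q.start)
        counts[i] = int(np.count_nonzero(ov >= min_overlap))
    return counts


def overlaps_any(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> np.ndarray:
    """Boolean flag per query: does it share >= ``min_overlap`` bases with any
    subject interval? Half-open semantics, so abutting intervals never overlap.
    """
    return overlap_counts(query, subject, min_overlap) > 0


def extend(
    intervals: Sequence[GenomicInterval],
    flank: int,
    sizes: ChromSizes,
) -> list[GenomicInterval]:
    """Grow each interval by ``flank`` bases on both sides, clipped to the
    chromosome."""
    if flank < 0:
        raise ParameterError(f"flank must be >= 0, got {flank}")
    _validate_all(intervals, sizes)
    out = []
    for iv in intervals:
        start, end = sizes.clip(iv.chrom, iv.start - flank, iv.end + flank)
        out.append(replace(iv, start=start, end=end))
    return out


def promoter_windows(
    genes: Sequence[GeneRecord],
    upstream: int = 2000,
    downstream: int = 500,
    sizes: ChromSizes | None = None,
) -> list[GenomicInterval]:
    """Strand-aware promoter windows around protein-coding TSSs.

    The window covers ``upstream`` bases 5' of the TSS plus ``downstream``
    bases starting at (and including) the TSS itself. Non-protein-coding
    genes yield no window; unstranded genes are rejected.
    """
    windows: list[GenomicInterval] = []
    for gene in genes:
        if not gene.is_protein_coding:
            continue
        tss = gene.tss  # raises CoordinateError on strand "."
        if gene.interval.strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream + 1, tss + upstream + 1
        if sizes is not None:
            start, end = sizes.clip(gene.interval.chrom, start, end)
        else:
            start = max(0, start)
        windows.append(GenomicInterval(gene.interval.chrom, start, end))
    return windows


def total_covered(intervals: Sequence[GenomicInterval]) -> int:
    """Total number of distinct bases covered by the interval set."""
    return sum(iv.length for iv in merge_within(intervals, max_gap=0))
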