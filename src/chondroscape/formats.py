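"""Readers/writers for the text formats the pipeline consumes, plus coverage
quantification against step-function tracks.

Supported formats: BED3/BED6, narrowPeak (BED6+4, extra columns preserved),
4-column bedGraph, tab-separated gene tables, and TSV signal matrices with a
``chrom start end <condition...>`` header. Coverage values are serialized with
6 significant digits.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    ChromSizes,
    CoordinateError,
    GeneRecord,
    GenomicInterval,
    ParameterError,
)

__all__ = [
    "FormatError",
    "CoverageTrack",
    "SignalMatrix",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "quantify",
]

_FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A file violates its format contract."""


# ---------------------------------------------------------------------------
# interval formats


def _normalize_chroms(df: pd.DataFrame, sizes: ChromSizes | None) -> pd.DataFrame:
    if sizes is not None:
        df = df.copy()
        df["chrom"] = [sizes.normalize(c) for c in df["chrom"]]
    return df


def read_bed(path: str | Path, sizes: ChromSizes | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; score column maps to ``score``."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >= 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df = _normalize_chroms(df, sizes)
    out = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "_5", ".") if df.shape[1] >= 6 else "."
        score = float(getattr(row, "_4")) if df.shape[1] >= 5 else None
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end),
                             strand if strand in "+-." else ".", score)
        if sizes is not None:
            sizes.validate(iv)
        out.append(iv)
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write BED3 (no names/scores) or BED6 when names are given or any
    interval carries a score/strand."""
    six = names is not None or any(
        iv.score is not None or iv.strand != "." for iv in intervals
    )
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if six:
                name = names[i] if names is not None else f"region_{i}"
                score = _FLOAT_FMT % iv.score if iv.score is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(
    path: str | Path, sizes: ChromSizes | None = None
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Read narrowPeak; returns intervals plus the full table (columns 7-10
    preserved when present)."""
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "signalValue", "pValue", "qValue", "peak",
    ]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return [], pd.DataFrame(columns=cols)
    df.columns = cols[: df.shape[1]]
    df = _normalize_chroms(df, sizes)
    out = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand", ".")
        score = float(getattr(row, "score", 0.0)) if "score" in df.columns else None
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end),
                             strand if strand in "+-." else ".", score)
        if sizes is not None:
            sizes.validate(iv)
        out.append(iv)
    return out, df


def write_narrowpeak(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def intervals_to_narrowpeak(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    signal: Sequence[float] | None = None,
    name_prefix: str = "peak",
) -> None:
    """Write intervals as 10-column narrowPeak (summit = midpoint)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            sig = signal[i] if signal is not None else (iv.score or 0.0)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}_{i}\t"
                f"{int(round(min(1000, sig * 10)))}\t.\t{_FLOAT_FMT % sig}\t"
                f"-1\t-1\t{iv.length // 2}\n"
            )


# ---------------------------------------------------------------------------
# gene tables


def read_gene_table(path: str | Path, sizes: ChromSizes | None = None) -> list[GeneRecord]:
    """Tab-separated gene table: chrom, start, end, strand, name, biotype."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "strand", "name", "biotype"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: gene table needs columns {sorted(required)}")
    df = _normalize_chroms(df, sizes)
    genes = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        if sizes is not None:
            sizes.validate(iv)
        genes.append(GeneRecord(iv, str(row.name), str(row.biotype)))
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.interval.strand,
            "name": g.name,
            "biotype": g.biotype,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return ChromSizes(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sizes:
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# coverage tracks


@dataclass
class CoverageTrack:
    """Per-chromosome step function of normalized signal (units per bp).

    Stored as sorted, non-overlapping ``(starts, ends, values)`` segments per
    chromosome; bases not covered by a segment read as zero. ``label`` names
    the condition (e.g. ``limb_pos_H3K27ac``); ``normalization_factor`` records
    the reads-per-million scalar actually applied (1.0 when pre-normalized).
    """

    sizes: ChromSizes
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    label: str = ""
    normalization_factor: float = 1.0

    def value_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over ``[start, end)``."""
        if chrom not in self.segments:
            return 0.0
        starts, ends, values = self.segments[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(values[lo:hi] * np.maximum(ov, 0)))

    def mean(self, interval: GenomicInterval) -> float:
        self.sizes.validate(interval)
        return self.value_sum(interval.chrom, interval.start, interval.end) / interval.length

    def scaled(self, factor: float, label: str | None = None) -> "CoverageTrack":
        """Multiply every value by ``factor`` (used by :func:`normalize_track`)."""
        segs = {
            chrom: (s.copy(), e.copy(), v * factor)
            for chrom, (s, e, v) in self.segments.items()
        }
        return CoverageTrack(
            self.sizes, segs, label or self.label,
            self.normalization_factor * factor,
        )

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.sizes:
                if chrom not in self.segments:
                    continue
                starts, ends, values = self.segments[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{_FLOAT_FMT % v}\n")


def read_bedgraph(
    path: str | Path, sizes: ChromSizes, label: str = ""
) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Input intervals may be unsorted; overlapping intervals are a format error;
    gaps read as zero. Negative values and off-chromosome intervals are
    rejected.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "value"], comment="#",
        )
    except pd.errors.EmptyDataError:
        return CoverageTrack(sizes, {}, label)
    if df["value"].lt(0).any():
        raise FormatError(f"{path}: negative coverage value")
    df["chrom"] = [sizes.normalize(c) for c in df["chrom"]]
    segments = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        if (starts < 0).any() or (ends > sizes[chrom]).any() or (ends <= starts).any():
            raise CoordinateError(f"{path}: off-chromosome or empty interval on {chrom}")
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            raise FormatError(f"{path}: overlapping intervals on {chrom}")
        segments[chrom] = (starts, ends, grp["value"].to_numpy(dtype=float))
    return CoverageTrack(sizes, segments, label)


def normalize_track(raw: CoverageTrack, million_scale: float) -> CoverageTrack:
    """Divide every value by ``million_scale`` (reads-per-million scaling);
    the applied factor is recorded on the returned track."""
    if million_scale <= 0:
        raise ParameterError(f"million_scale must be > 0, got {million_scale}")
    return raw.scaled(1.0 / million_scale)


def quantify(
    regions: Sequence[GenomicInterval], track: CoverageTrack
) -> np.ndarray:
    """Mean normalized signal per region: sum of per-base signal / length."""
    return np.array([track.mean(iv) for iv in regions], dtype=float)


# ---------------------------------------------------------------------------
# signal matrices


@dataclass
class SignalMatrix:
    """Mean normalized coverage per region x condition."""

    regions: list[GenomicInterval]
    conditions: list[str]
    values: np.ndarray  # shape (n_regions, n_conditions), >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.conditions)):
            raise FormatError("SignalMatrix shape mismatch")
        if (self.values < 0).any():
            raise FormatError("SignalMatrix values must be >= 0")

    def column(self, condition: str) -> np.ndarray:
        return self.values[:, self.conditions.index(condition)]

    @classmethod
    def from_tracks(
        cls,
        regions: Sequence[GenomicInterval],
        tracks: Mapping[str, CoverageTrack],
    ) -> "SignalMatrix":
        conditions = list(tracks)
        values = np.column_stack(
            [quantify(regions, tracks[c]) for c in conditions]
        ) if conditions and len(regions) else np.zeros((len(regions), len(conditions)))
        return cls(list(regions), conditions, values)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.regions],
                "start": [iv.start for iv in self.regions],
                "end": [iv.end for iv in self.regions],
            }
        )
        for j, cond in enumerate(self.conditions):
            df[cond] = [_FLOAT_FMT % v for v in self.values[:, j]]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sizes: ChromSizes | None = None) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t")
        base = ["chrom", "start", "end"]
        if df.columns.tolist()[:3] != base:
            raise FormatError(f"{path}: expected header chrom start end <conditions>")
        df = _normalize_chroms(df, sizes)
        regions = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in df[base].itertuples(index=False)
        ]
        conditions = [c for c in df.columns if c not in base]
        return cls(regions, conditions, df[conditions].to_numpy(dtype=float))
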