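"""Cumulative height-variance attribution to enhancer sets.

Genome-wide-significant (GWS) height loci are non-overlapping segments, each
carrying the fraction of phenotypic height variance explained by its
significant variants. Loci are split into protein-coding and non-coding by
gene overlap; enhancer sets are size-matched by taking the top-k (877 by
default) autosomal enhancers ranked by their strongest between-fraction
H3K27ac signal; the cumulative curve walks loci from highest to lowest
variance, accumulating every locus on x and only enhancer-overlapped loci
on y — so y <= x everywhere and the final y is the total variance the set
can explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enhancers import AggregatedEnhancer, pct
from .intervals import (
    ChromSizes,
    GeneRecord,
    GenomicInterval,
    ParameterError,
    overlaps_any,
)

__all__ = [
    "GWSLocus",
    "VarianceCurve",
    "split_coding",
    "top_k_enhancers",
    "cumulative_curve",
    "compare_sets",
    "read_gws_loci",
    "plot_curves",
]


@dataclass(frozen=True)
class GWSLocus:
    """A height-associated locus with its explained-variance weight."""

    interval: GenomicInterval
    variance_explained: float
    coding: bool | None = None

    def __post_init__(self) -> None:
        if self.variance_explained < 0:
            raise ParameterError("variance_explained must be >= 0")


@dataclass
class VarianceCurve:
    """Cumulative locus variance (x) vs enhancer-attributed variance (y)."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if (np.diff(self.x) < 0).any() or (np.diff(self.y) < 0).any():
            raise ParameterError("curve coordinates must be non-decreasing")
        if (self.y > self.x + 1e-12).any():
            raise ParameterError("attributed variance cannot exceed locus variance")


def read_gws_loci(path, sizes: ChromSizes | None = None) -> list[GWSLocus]:
    """Read a GWS-locus TSV (chrom, start, end, variance_explained)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "variance_explained"}
    if not required <= set(df.columns):
        raise ParameterError(f"{path}: loci table needs columns {sorted(required)}")
    loci = []
    for row in df.itertuples(index=False):
        chrom = sizes.normalize(row.chrom) if sizes is not None else row.chrom
        iv = GenomicInterval(chrom, int(row.start), int(row.end))
        if sizes is not None:
            sizes.validate(iv)
        loci.append(GWSLocus(iv, float(row.variance_explained)))
    return loci


def _check_loci_disjoint(loci: Sequence[GWSLocus]) -> None:
    ordered = sorted(loci, key=lambda l: l.interval.key())
    for a, b in zip(ordered, ordered[1:]):
        if (
            a.interval.chrom == b.interval.chrom
            and b.interval.start < a.interval.end
        ):
            raise ParameterError(f"overlapping GWS loci: {a.interval} / {b.interval}")


def split_coding(
    loci: Sequence[GWSLocus],
    protein_coding_genes: Sequence[GeneRecord],
) -> tuple[list[GWSLocus], list[GWSLocus]]:
    """Partition loci into (coding, non_coding) by any-overlap with a
    protein-coding gene body."""
    gene_ivs = [
        g.interval for g in protein_coding_genes if g.is_protein_coding
    ]
    flags = (
        overlaps_any([l.interval for l in loci], gene_ivs)
        if gene_ivs and loci
        else np.zeros(len(loci), dtype=bool)
    )
    coding = [GWSLocus(l.interval, l.variance_explained, True)
              for l, f in zip(loci, flags) if f]
    non_coding = [GWSLocus(l.interval, l.variance_explained, False)
                  for l, f in zip(loci, flags) if not f]
    return coding, non_coding


def top_k_enhancers(
    enhancers: Sequence[AggregatedEnhancer],
    k: int = 877,
    sizes: ChromSizes | None = None,
    metric: str = "fold_change",
) -> list[AggregatedEnhancer]:
    """Size-match an enhancer set: autosomal enhancers ranked by the maximum
    over tissues of the EGFP+/EGFP− fold change (or coverage difference when
    ``metric="coverage_diff"``), top ``k`` kept, ties broken by coordinates.

    If fewer than ``k`` candidates exist the whole set is returned with a
    warning.
    """
    if metric not in ("fold_change", "coverage_diff"):
        raise ParameterError(f"unknown ranking metric {metric!r}")
    pool = [
        e for e in enhancers
        if sizes is None or sizes.is_autosome(e.interval.chrom)
    ]
    keyfun = (
        (lambda e: e.max_fold_change)
        if metric == "fold_change"
        else (lambda e: e.max_coverage_diff)
    )
    ranked = sorted(pool, key=lambda e: (-keyfun(e),) + e.interval.key())
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} autosomal enhancers available for top-{k}",
            stacklevel=2,
        )
        return ranked
    return ranked[:k]


def cumulative_curve(
    loci: Sequence[GWSLocus],
    enhancer_set: Sequence[GenomicInterval | AggregatedEnhancer],
    label: str = "",
) -> tuple[VarianceCurve, dict]:
    """Walk loci from highest to lowest variance, accumulating every locus's
    variance on x and, on y, the variance of loci overlapped by >= 1 enhancer
    of the set (counted once per locus however many enhancers overlap it)."""
    _check_loci_disjoint(loci)
    ivs = [
        e.interval if isinstance(e, AggregatedEnhancer) else e
        for e in enhancer_set
    ]
    ordered = sorted(
        loci, key=lambda l: (-l.variance_explained,) + l.interval.key()
    )
    flags = (
        overlaps_any([l.interval for l in ordered], ivs)
        if ivs and ordered
        else np.zeros(len(ordered), dtype=bool)
    )
    variances = np.array([l.variance_explained for l in ordered], dtype=float)
    x = np.cumsum(variances)
    y = np.cumsum(np.where(flags, variances, 0.0))
    curve = VarianceCurve(x, y, label)
    n_hit = int(flags.sum())
    totals = {
        "n_loci": len(ordered),
        "n_overlapped": n_hit,
        "pct_loci_overlapped": pct(n_hit, len(ordered), decimals=1) if ordered else 0.0,
        "x_total": float(x[-1]) if len(x) else 0.0,
        "y_total": float(y[-1]) if len(y) else 0.0,
    }
    totals["fraction_of_variance"] = (
        totals["y_total"] / totals["x_total"] if totals["x_total"] > 0 else 0.0
    )
    return curve, totals


def compare_sets(
    loci: Sequence[GWSLocus],
    named_enhancer_sets: Mapping[str, Sequence[AggregatedEnhancer | GenomicInterval]],
) -> pd.DataFrame:
    """One cumulative-attribution row per (size-matched) enhancer set."""
    rows = []
    for name, enh_set in named_enhancer_sets.items():
        _, totals = cumulative_curve(loci, enh_set, label=name)
        rows.append({"set": name, **totals})
    return pd.DataFrame(rows).set_index("set")


def plot_curves(curves: Sequence[VarianceCurve], path) -> None:
    """Plot cumulative variance curves (x = locus variance, y = attributed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        ax.plot(
            np.concatenate([[0.0], curve.x]),
            np.concatenate([[0.0], curve.y]),
            label=curve.label or None,
        )
    lim = max((float(c.x[-1]) for c in curves if len(c.x)), default=1.0)
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("cumulative variance of GWS loci")
    ax.set_ylabel("cumulative variance attributed to enhancers")
    if any(c.label for c in curves):
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
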