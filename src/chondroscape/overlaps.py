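"""Transcription-factor-binding overlap analysis and discrete-locus counting.

``tf_overlap`` measures the fraction of enhancers touched by TF ChIP peaks
(any-overlap, 1 bp) against a merged inactive-region control set.
``locus_overlap_counts`` tallies enhancers and chondrogenic genes inside a
small set of large named loci (e.g. stature-associated TAD spans).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .enhancers import pct
from .intervals import (
    GeneRecord,
    GenomicInterval,
    ParameterError,
    merge_within,
    overlaps_any,
)

__all__ = ["OverlapReport", "prepare_control", "tf_overlap", "locus_overlap_counts"]


@dataclass(frozen=True)
class OverlapReport:
    n_query: int
    n_overlapping: int
    fraction: float  # integer percent of queries overlapped
    control_n: int
    control_overlapping: int
    control_fraction: float  # percent to one decimal

    def __post_init__(self) -> None:
        if not 0 <= self.n_overlapping <= self.n_query:
            raise ParameterError("n_overlapping outside [0, n_query]")


def prepare_control(
    inactive_regions: Sequence[GenomicInterval], merge_gap: int = 500
) -> list[GenomicInterval]:
    """Merge accessible-but-inactive regions within 500 bp into a control set."""
    return merge_within(inactive_regions, merge_gap)


def tf_overlap(
    enhancers: Sequence[GenomicInterval],
    tf_peaks: Sequence[GenomicInterval],
    control: Sequence[GenomicInterval],
) -> OverlapReport:
    """Fraction of enhancers (and control regions) overlapped by TF peaks.

    TF peaks are expected pre-merged within 500 bp. The query fraction is
    reported as an integer percent, the control fraction to one decimal.
    """
    if not enhancers:
        raise ParameterError("empty enhancer query set")
    n_hit = int(overlaps_any(enhancers, tf_peaks).sum()) if tf_peaks else 0
    n_ctrl_hit = (
        int(overlaps_any(control, tf_peaks).sum()) if tf_peaks and control else 0
    )
    return OverlapReport(
        n_query=len(enhancers),
        n_overlapping=n_hit,
        fraction=pct(n_hit, len(enhancers)),
        control_n=len(control),
        control_overlapping=n_ctrl_hit,
        control_fraction=pct(n_ctrl_hit, len(control), decimals=1) if control else 0.0,
    )


def locus_overlap_counts(
    loci: Mapping[str, GenomicInterval],
    chondro_enhancers: Sequence[GenomicInterval],
    non_chondro_enhancers: Sequence[GenomicInterval],
    chondro_genes: Sequence[GeneRecord] = (),
) -> dict:
    """Per-locus and total enhancer/gene content of large named loci.

    Loci may overlap each other; an enhancer falling in several loci is
    counted once in the totals (deduplication by enhancer identity). Total
    percentages are reported to one decimal of each enhancer universe.
    """
    per_locus: dict[str, dict] = {}
    hit_chondro: set[int] = set()
    hit_non: set[int] = set()
    for name, locus in loci.items():
        c_ids = [
            i for i, e in enumerate(chondro_enhancers) if e.overlap_len(locus) >= 1
        ]
        n_ids = [
            i for i, e in enumerate(non_chondro_enhancers) if e.overlap_len(locus) >= 1
        ]
        genes = sorted(
            g.name for g in chondro_genes if g.interval.overlap_len(locus) >= 1
        )
        hit_chondro.update(c_ids)
        hit_non.update(n_ids)
        per_locus[name] = {
            "n_chondrogenic": len(c_ids),
            "n_non_chondrogenic": len(n_ids),
            "chondro_genes": genes,
        }
    totals = {
        "n_chondrogenic": len(hit_chondro),
        "n_non_chondrogenic": len(hit_non),
    }
    if chondro_enhancers:
        totals["pct_chondrogenic"] = pct(
            len(hit_chondro), len(chondro_enhancers), decimals=1
        )
    if non_chondro_enhancers:
        totals["pct_non_chondrogenic"] = pct(
            len(hit_non), len(non_chondro_enhancers), decimals=1
        )
    return {"per_locus": per_locus, "totals": totals}
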