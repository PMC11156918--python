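"""Differential-activity enhancer calling and tissue-specificity classification.

The calling rule operates on accessible, promoter-distal H3K27ac peaks from
sorted EGFP+ (chondrocyte) vs EGFP− (other) cell fractions of one tissue:

* chondrogenic:     cov+ >= 0.5  and  cov+ / max(cov−, pc) >= 4
* non-chondrogenic: cov− >= 0.5  and  cov− / max(cov+, pc) >= 4

Surviving calls of each class are merged within 500 bp. Chondrogenic calls
from the two tissues (limb, trunk) are then aggregated and classified as
limb-enriched, trunk-enriched or pan-chondrogenic by a 2-fold H3K27ac
coverage ratio between tissues. Marker genes are classified from a
differential-expression table with |log2FC| > 1.5 and BH-adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import CoverageTrack, quantify
from .intervals import (
    ChromSizes,
    GenomicInterval,
    ParameterError,
    extend,
    merge_within,
    overlaps_any,
    sort_intervals,
)

__all__ = [
    "CallingParams",
    "EnhancerCall",
    "AggregatedEnhancer",
    "GeneSpecificity",
    "consensus_atac",
    "candidate_regions",
    "call_differential",
    "classify_tissue",
    "classify_genes",
    "summarize_landscape",
    "pct",
]

CHONDROGENIC = "chondrogenic"
NON_CHONDROGENIC = "non_chondrogenic"
TISSUE_CLASSES = ("limb_enriched", "trunk_enriched", "pan")


@dataclass(frozen=True)
class CallingParams:
    """Thresholds of the enhancer-calling procedure.

    atac_flank      bp added to each side of consensus ATAC peaks
    promoter_up/down  promoter-exclusion window around protein-coding TSSs
    fc_threshold    minimal EGFP+/EGFP− (or mirrored) H3K27ac coverage ratio
    min_pos_cov     absolute coverage floor on the enriched fraction
    merge_gap       bp within which surviving calls of one class are merged
    tissue_fc       between-tissue ratio separating enriched from pan
    pseudocount     denominator floor for ratios (signal units)
    """

    atac_flank: int = 150
    promoter_up: int = 2000
    promoter_down: int = 500
    fc_threshold: float = 4.0
    min_pos_cov: float = 0.5
    merge_gap: int = 500
    tissue_fc: float = 2.0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "atac_flank", "promoter_up", "promoter_down", "fc_threshold",
            "min_pos_cov", "merge_gap", "tissue_fc", "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class EnhancerCall:
    """A called enhancer in one tissue with its provenance coverages."""

    interval: GenomicInterval
    tissue_of_call: str  # "limb" | "trunk"
    activity: str  # CHONDROGENIC | NON_CHONDROGENIC
    cov_pos: float
    cov_neg: float
    fold_change: float


@dataclass(frozen=True)
class AggregatedEnhancer:
    """A merged cross-tissue chondrogenic enhancer with its tissue class.

    ``cov_limb``/``cov_trunk`` are mean EGFP+ H3K27ac coverages over the
    aggregated region; ``fc_limb``/``fc_trunk`` the EGFP+/EGFP− ratios used
    downstream for size-matched set selection.
    """

    interval: GenomicInterval
    cov_limb: float
    cov_trunk: float
    tissue_class: str  # one of TISSUE_CLASSES
    fc_limb: float = float("nan")
    fc_trunk: float = float("nan")
    diff_limb: float = float("nan")
    diff_trunk: float = float("nan")

    @property
    def max_fold_change(self) -> float:
        return float(np.nanmax([self.fc_limb, self.fc_trunk]))

    @property
    def max_coverage_diff(self) -> float:
        return float(np.nanmax([self.diff_limb, self.diff_trunk]))


@dataclass(frozen=True)
class GeneSpecificity:
    """Per-gene marker status in each tissue and cross-tissue class."""

    gene: str
    marker_class: Mapping[str, str]  # tissue -> egfp_pos_marker|egfp_neg_marker|none
    tissue_class: str | None  # limb_specific | trunk_specific | shared | None
    missing_in: tuple[str, ...] = ()

    @property
    def is_chondrogenic(self) -> bool:
        return any(v == "egfp_pos_marker" for v in self.marker_class.values())


def consensus_atac(
    rep1: Sequence[GenomicInterval],
    rep2: Sequence[GenomicInterval],
    sizes: ChromSizes,
    params: CallingParams = CallingParams(),
) -> list[GenomicInterval]:
    """Reproducible accessible regions: peaks of either replicate that overlap
    (>= 1 bp) a peak of the other, merged, then extended by ``atac_flank``."""
    if not rep1 or not rep2:
        warnings.warn("empty ATAC replicate: consensus is empty", stacklevel=2)
        return []
    keep1 = [iv for iv, f in zip(rep1, overlaps_any(rep1, rep2)) if f]
    keep2 = [iv for iv, f in zip(rep2, overlaps_any(rep2, rep1)) if f]
    merged = merge_within(keep1 + keep2, max_gap=0, sizes=sizes)
    return extend(merged, params.atac_flank, sizes)


def candidate_regions(
    h3k27ac_peaks: Sequence[GenomicInterval],
    atac_consensus: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """H3K27ac peaks overlapping accessible consensus and no promoter window.

    The surviving peak keeps its own footprint (the intersection is a filter,
    not a clip).
    """
    peaks = sort_intervals(h3k27ac_peaks)
    if not peaks:
        return []
    accessible = overlaps_any(peaks, atac_consensus) if atac_consensus else np.zeros(len(peaks), bool)
    promoter_hit = overlaps_any(peaks, promoters) if promoters else np.zeros(len(peaks), bool)
    return [p for p, a, pr in zip(peaks, accessible, promoter_hit) if a and not pr]


def _merge_calls(
    members: list[tuple[GenomicInterval, float, float]],
    tissue: str,
    activity: str,
    params: CallingParams,
) -> list[EnhancerCall]:
    """Merge surviving candidate calls of one class within ``merge_gap``.

    The merged call's per-fraction coverages are the max over members and the
    fold change is recomputed from those maxima.
    """
    members = sorted(members, key=lambda m: m[0].key())
    groups: list[list[tuple[GenomicInterval, float, float]]] = []
    for m in members:
        if (
            groups
            and m[0].chrom == groups[-1][-1][0].chrom
            and m[0].start - max(x[0].end for x in groups[-1]) <= params.merge_gap
        ):
            groups[-1].append(m)
        else:
            groups.append([m])
    calls = []
    for grp in groups:
        iv = GenomicInterval(
            grp[0][0].chrom,
            min(x[0].start for x in grp),
            max(x[0].end for x in grp),
        )
        cov_pos = max(x[1] for x in grp)
        cov_neg = max(x[2] for x in grp)
        if activity == CHONDROGENIC:
            fc = cov_pos / max(cov_neg, params.pseudocount)
        else:
            fc = cov_neg / max(cov_pos, params.pseudocount)
        calls.append(EnhancerCall(iv, tissue, activity, cov_pos, cov_neg, fc))
    return calls


def call_differential(
    candidates: Sequence[GenomicInterval],
    cov_pos: Sequence[float],
    cov_neg: Sequence[float],
    params: CallingParams = CallingParams(),
    tissue: str = "limb",
) -> list[EnhancerCall]:
    """Apply the fold-change + coverage-floor rule per candidate, then merge
    surviving calls of each activity class separately within ``merge_gap``."""
    cov_pos = np.asarray(cov_pos, dtype=float)
    cov_neg = np.asarray(cov_neg, dtype=float)
    if len(candidates) != len(cov_pos) or len(candidates) != len(cov_neg):
        raise ParameterError("one coverage value per candidate per fraction required")
    if (cov_pos < 0).any() or (cov_neg < 0).any():
        raise ValueError("negative coverage")
    pc = params.pseudocount
    chondro, non_chondro = [], []
    for iv, cp, cn in zip(candidates, cov_pos, cov_neg):
        if cp >= params.min_pos_cov and cp / max(cn, pc) >= params.fc_threshold:
            chondro.append((iv, float(cp), float(cn)))
        elif cn >= params.min_pos_cov and cn / max(cp, pc) >= params.fc_threshold:
            non_chondro.append((iv, float(cp), float(cn)))
    return _merge_calls(chondro, tissue, CHONDROGENIC, params) + _merge_calls(
        non_chondro, tissue, NON_CHONDROGENIC, params
    )


def classify_tissue(
    limb_calls: Sequence[EnhancerCall],
    trunk_calls: Sequence[EnhancerCall],
    limb_pos_track: CoverageTrack,
    trunk_pos_track: CoverageTrack,
    params: CallingParams = CallingParams(),
    limb_neg_track: CoverageTrack | None = None,
    trunk_neg_track: CoverageTrack | None = None,
) -> list[AggregatedEnhancer]:
    """Aggregate chondrogenic calls across tissues and classify each merged
    region as limb-enriched, trunk-enriched or pan-chondrogenic.

    Classification compares mean EGFP+ H3K27ac coverage over the aggregated
    region between tissues at the ``tissue_fc`` (2-fold) threshold, flooring
    denominators at ``pseudocount``. When the EGFP− tracks are supplied, the
    per-tissue EGFP+/EGFP− fold changes and coverage differences are attached
    for downstream size-matched ranking.
    """
    chondro = [c.interval for c in list(limb_calls) + list(trunk_calls)
               if c.activity == CHONDROGENIC]
    if not chondro:
        return []
    regions = merge_within(chondro, max_gap=0)
    cov_limb = quantify(regions, limb_pos_track)
    cov_trunk = quantify(regions, trunk_pos_track)
    neg_limb = quantify(regions, limb_neg_track) if limb_neg_track else None
    neg_trunk = quantify(regions, trunk_neg_track) if trunk_neg_track else None
    pc = params.pseudocount
    out = []
    for i, iv in enumerate(regions):
        cl, ct = float(cov_limb[i]), float(cov_trunk[i])
        if cl / max(ct, pc) >= params.tissue_fc:
            klass = "limb_enriched"
        elif ct / max(cl, pc) >= params.tissue_fc:
            klass = "trunk_enriched"
        else:
            klass = "pan"
        fc_l = cl / max(float(neg_limb[i]), pc) if neg_limb is not None else float("nan")
        fc_t = ct / max(float(neg_trunk[i]), pc) if neg_trunk is not None else float("nan")
        d_l = cl - float(neg_limb[i]) if neg_limb is not None else float("nan")
        d_t = ct - float(neg_trunk[i]) if neg_trunk is not None else float("nan")
        out.append(AggregatedEnhancer(iv, cl, ct, klass, fc_l, fc_t, d_l, d_t))
    return out


def classify_genes(
    de_tables: Mapping[str, pd.DataFrame],
    log2fc_threshold: float = 1.5,
    padj_threshold: float = 0.05,
) -> list[GeneSpecificity]:
    """Classify marker genes from per-tissue EGFP+ vs EGFP− DE tables.

    A gene is an EGFP+ marker in a tissue iff log2FC > 1.5 and BH-adjusted
    p < 0.05 (strict inequalities); EGFP− markers mirror the rule. Among
    genes that are EGFP+ markers in at least one tissue, the cross-tissue
    class is limb_specific / trunk_specific / shared. Genes absent from one
    tissue's table are non-markers there and flagged in ``missing_in``.
    """
    tissues = list(de_tables)
    tables = {}
    for tissue, df in de_tables.items():
        if not {"gene", "log2FC", "padj"} <= set(df.columns):
            raise ParameterError("DE table needs columns gene, log2FC, padj")
        tables[tissue] = df.set_index("gene")[["log2FC", "padj"]]
    all_genes = sorted(set().union(*(t.index for t in tables.values())))
    out = []
    for gene in all_genes:
        marker: dict[str, str] = {}
        missing = []
        for tissue in tissues:
            t = tables[tissue]
            if gene not in t.index:
                marker[tissue] = "none"
                missing.append(tissue)
                continue
            lfc, padj = float(t.at[gene, "log2FC"]), float(t.at[gene, "padj"])
            if lfc > log2fc_threshold and padj < padj_threshold:
                marker[tissue] = "egfp_pos_marker"
            elif lfc < -log2fc_threshold and padj < padj_threshold:
                marker[tissue] = "egfp_neg_marker"
            else:
                marker[tissue] = "none"
        pos_in = [t for t in tissues if marker[t] == "egfp_pos_marker"]
        if not pos_in:
            klass = None
        elif set(pos_in) == {"limb"}:
            klass = "limb_specific"
        elif set(pos_in) == {"trunk"}:
            klass = "trunk_specific"
        else:
            klass = "shared"
        out.append(GeneSpecificity(gene, marker, klass, tuple(missing)))
    return out


def pct(numerator: int | float, denominator: int | float, decimals: int = 0) -> float:
    """Percentage rounded to the printed precision (integer by default)."""
    if denominator == 0:
        raise ParameterError("percentage with zero denominator")
    value = round(100.0 * numerator / denominator, decimals)
    return int(value) if decimals == 0 else value


def summarize_landscape(
    aggregated: Sequence[AggregatedEnhancer],
    per_tissue_calls: Mapping[str, Sequence[EnhancerCall]] | None = None,
    gene_classes: Sequence[GeneSpecificity] | None = None,
    non_chondro: Sequence[GenomicInterval] | None = None,
) -> dict:
    """Counts and printed-precision percentages of the enhancer landscape."""
    summary: dict = {}
    n_chondro = len(aggregated)
    counts = {k: sum(1 for a in aggregated if a.tissue_class == k) for k in TISSUE_CLASSES}
    summary["n_chondrogenic"] = n_chondro
    summary["tissue_class_counts"] = counts
    if n_chondro:
        summary["tissue_class_pct"] = {k: pct(v, n_chondro) for k, v in counts.items()}
    if non_chondro is not None:
        n_non = len(non_chondro)
        total = n_chondro + n_non
        summary["n_non_chondrogenic"] = n_non
        summary["n_total"] = total
        if total:
            summary["pct_chondrogenic_of_total"] = pct(n_chondro, total)
            summary["pct_non_chondrogenic_of_total"] = pct(n_non, total)
    if gene_classes is not None:
        chondro_genes = [g for g in gene_classes if g.is_chondrogenic]
        gc = {
            "shared": sum(1 for g in chondro_genes if g.tissue_class == "shared"),
            "limb_specific": sum(1 for g in chondro_genes if g.tissue_class == "limb_specific"),
            "trunk_specific": sum(1 for g in chondro_genes if g.tissue_class == "trunk_specific"),
        }
        summary["n_chondrogenic_genes"] = len(chondro_genes)
        summary["gene_class_counts"] = gc
        if chondro_genes:
            summary["gene_class_pct"] = {
                k: pct(v, len(chondro_genes)) for k, v in gc.items()
            }
    if per_tissue_calls is not None:
        summary["per_tissue"] = {
            tissue: {
                "chondrogenic": sum(1 for c in calls if c.activity == CHONDROGENIC),
                "non_chondrogenic": sum(1 for c in calls if c.activity == NON_CHONDROGENIC),
            }
            for tissue, calls in per_tissue_calls.items()
        }
    return summary
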