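"""TAD-based enhancer/gene bookkeeping and per-category statistics.

Enhancers are assigned to topologically associating domains only when they
overlap exactly one TAD (boundary-straddling or inter-TAD enhancers stay
unassigned). A TAD with >= 1 chondrogenic enhancer is a *chondroTAD* when it
also holds >= 1 protein-coding chondrogenic gene, a *chondroEnhTAD* otherwise;
TADs without chondrogenic enhancers are *other*. Enhancer counts per TAD are
compared between categories with a two-tailed Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GeneRecord,
    GenomicInterval,
    ParameterError,
    overlap_counts,
    sort_intervals,
)

__all__ = [
    "TADRecord",
    "assign_enhancers",
    "categorize",
    "per_tad_stats",
    "rank_sum_test",
    "concordance_table",
]

CHONDRO_TAD = "chondroTAD"
CHONDRO_ENH_TAD = "chondroEnhTAD"
OTHER = "other"


@dataclass(frozen=True)
class TADRecord:
    interval: GenomicInterval
    enhancer_ids: tuple[int, ...]
    chondro_gene_names: tuple[str, ...]
    category: str

    @property
    def n_enhancers(self) -> int:
        return len(self.enhancer_ids)


def _check_disjoint(tads: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    ordered = sort_intervals(tads)
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ParameterError(f"overlapping TADs: {a} / {b}")
    return ordered


def assign_enhancers(
    enhancers: Sequence[GenomicInterval],
    tads: Sequence[GenomicInterval],
) -> tuple[dict[int, list[int]], list[int]]:
    """Assign each enhancer to the unique TAD it overlaps.

    Returns ``(assignments, unassigned)`` where ``assignments`` maps the index
    of a TAD (in the input order) to indices of its enhancers, and
    ``unassigned`` lists enhancers overlapping zero or >= 2 TADs. Overlapping
    TADs are rejected.
    """
    _check_disjoint(tads)
    n_over = overlap_counts(enhancers, tads)
    assignments: dict[int, list[int]] = {}
    unassigned: list[int] = []
    for i, (enh, n) in enumerate(zip(enhancers, n_over)):
        if n != 1:
            unassigned.append(i)
            continue
        for j, tad in enumerate(tads):
            if enh.overlap_len(tad) >= 1:
                assignments.setdefault(j, []).append(i)
                break
    return assignments, unassigned


def categorize(
    tads: Sequence[GenomicInterval],
    assignments: Mapping[int, Sequence[int]],
    chondro_genes: Sequence[GeneRecord],
) -> list[TADRecord]:
    """Categorize TADs given enhancer assignments and chondrogenic genes.

    Genes attach to a TAD by any overlap of the gene body; only protein-coding
    genes count toward the chondroTAD criterion.
    """
    coding = [g for g in chondro_genes if g.is_protein_coding]
    gene_ivs = [g.interval for g in coding]
    records = []
    for j, tad in enumerate(tads):
        enh_ids = tuple(assignments.get(j, ()))
        # gene attachment: any overlap of the gene body with the TAD
        names = tuple(
            g.name for g in coding if g.interval.overlap_len(tad) >= 1
        )
        if not enh_ids:
            cat = OTHER
        elif names:
            cat = CHONDRO_TAD
        else:
            cat = CHONDRO_ENH_TAD
        records.append(TADRecord(tad, enh_ids, names, cat))
    return records


def per_tad_stats(records: Sequence[TADRecord]) -> dict:
    """Per-category TAD counts and enhancer-count distribution summaries.

    Means are reported to one decimal (the printed precision); categories with
    no TADs report no mean/median.
    """
    out: dict = {}
    for cat in (CHONDRO_TAD, CHONDRO_ENH_TAD, OTHER):
        counts = [r.n_enhancers for r in records if r.category == cat]
        entry: dict = {
            "n_tads": len(counts),
            "n_enhancers": int(sum(counts)),
        }
        if counts:
            entry["mean_enhancers"] = round(float(np.mean(counts)), 1)
            entry["median_enhancers"] = float(np.median(counts))
        out[cat] = entry
    return out


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-tailed Mann-Whitney p by dynamic programming over rank sums.

    Midranks are doubled so tied ranks stay integral; the DP counts, for every
    subset of size ``len(x)`` of the pooled sample, the number of subsets with
    each possible (doubled) rank sum — equivalent to full label enumeration.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.asarray(np.round(stats.rankdata(pooled) * 2), dtype=int)
    w_obs = int(ranks2[:n1].sum())
    max_sum = int(ranks2.sum())
    # dp[k][s] = number of k-subsets with doubled rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    counts = dp[n1]
    total = counts.sum()
    mu2 = n1 * (n1 + n2 + 1)  # doubled mean rank sum
    dev = abs(w_obs - mu2)
    sums = np.arange(max_sum + 1)
    p = counts[np.abs(sums - mu2) >= dev].sum() / total
    u_obs = (w_obs / 2.0) - n1 * (n1 + 1) / 2.0
    return float(u_obs), float(min(1.0, p))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` with U counted for the first sample. Exact enumeration
    (tie-aware) when ``min(n) <= 8``; otherwise the tie-corrected normal
    approximation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ParameterError("rank_sum_test requires two non-empty samples")
    if min(len(x), len(y)) <= 8:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def concordance_table(
    records: Sequence[TADRecord],
    gene_classes: Mapping[str, str],
    enhancer_classes: Mapping[int, str],
) -> tuple[pd.DataFrame, int]:
    """Joint gene-class x enhancer-content table over chondroTADs.

    ``gene_classes`` maps chondrogenic gene name -> limb_specific /
    trunk_specific / shared; ``enhancer_classes`` maps enhancer id ->
    limb_enriched / trunk_enriched / pan. A TAD's gene class is the unique
    class of its genes (TADs with mixed gene classes are excluded and counted
    separately); its enhancer content is the single class present or "mixed".
    Returns ``(table, n_mixed_gene_tads)``.
    """
    gene_label = {"limb_specific": "limb", "trunk_specific": "trunk", "shared": "pan"}
    enh_label = {"limb_enriched": "limb", "trunk_enriched": "trunk", "pan": "pan"}
    rows = []
    n_mixed_genes = 0
    for rec in records:
        if rec.category != CHONDRO_TAD:
            continue
        gclasses = {
            gene_classes[name] for name in rec.chondro_gene_names
            if name in gene_classes
        }
        if len(gclasses) != 1:
            n_mixed_genes += 1
            continue
        eclasses = {
            enh_label[enhancer_classes[i]]
            for i in rec.enhancer_ids
            if i in enhancer_classes
        }
        if not eclasses:
            continue
        content = eclasses.pop() if len(eclasses) == 1 else "mixed"
        rows.append((gene_label[gclasses.pop()], content))
    table = pd.DataFrame(rows, columns=["gene_class", "enhancer_content"])
    table = (
        table.groupby(["gene_class", "enhancer_content"]).size().unstack(fill_value=0)
        if len(rows)
        else pd.DataFrame()
    )
    return table, n_mixed_genes
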