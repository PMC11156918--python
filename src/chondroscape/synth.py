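"""Synthetic-data generator: a complete, internally consistent input bundle
with ground-truth labels for every pipeline stage.

The generator emulates the sorted-population study design: two tissues (limb,
trunk) x two FACS fractions (EGFP+ chondrocytes, EGFP− rest), with

* replicated ATAC narrowPeak files (planted peaks with uniform edge jitter),
* one H3K27ac bedGraph per tissue x fraction (flat 0.05 baseline, planted
  regions at levels implying the intended fold changes, multiplicative
  log-normal noise),
* a gene table plus per-tissue differential-expression tables consistent with
  the intended marker labels,
* a TAD tiling whose domains are seeded with chondrogenic genes and/or
  enhancers (chondroTAD / chondroEnhTAD structure),
* TF ChIP peaks covering a set fraction of planted enhancers and 3% of
  inactive regions,
* a GWS-locus table with Pareto-tailed variance weights, high-variance loci
  planted over chondrogenic enhancers,
* eight named TAD-span stature loci,
* FASTA sequences with planted motif occurrences and a PCM file (one planted
  motif among random decoys).

Geometry guarantees that planted features never collide: every feature lives
in its own 6 kb slot, slots keep 2 kb clear of TAD boundaries, promoter
windows never reach a neighbouring slot's enhancer zone, and consensus-peak
extension plus the 500 bp call merge cannot bridge two slots.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import (
    CoverageTrack,
    intervals_to_narrowpeak,
    write_bed,
    write_chrom_sizes,
    write_gene_table,
)
from .intervals import ChromSizes, GeneRecord, GenomicInterval, ParameterError
from .motifs import PositionCountMatrix, read_fasta, read_pcms, reverse_complement, write_pcms

__all__ = ["SynthConfig", "SynthBundle", "generate", "validate_bundle"]

TISSUES = ("limb", "trunk")
FRACTIONS = ("pos", "neg")
CLASSES = ("pan", "limb", "trunk", "non_chondro", "subthreshold", "inactive")

_TAD_MARGIN = 2000
_SLOT_WIDTH = 6000


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic bundle.

    Class counts echo the landscape proportions of the system being emulated
    (74/18/8 pan/limb/trunk chondrogenic, ~25% non-chondrogenic); gene
    specificity fractions echo the 84/9/7 shared/limb/trunk marker split.
    Noise is multiplicative log-normal at ``noise_cv`` on region-level
    coverage; replicate ATAC peak edges jitter uniformly within
    ``jitter`` bp.
    """

    seed: int = 42
    n_chroms: int = 4              # autosomes; a half-length chrX is added
    chrom_length: int = 1_500_000
    tad_length: int = 50_000
    n_pan: int = 74
    n_limb: int = 18
    n_trunk: int = 8
    n_non_chondro: int = 33
    n_subthreshold: int = 20
    n_inactive: int = 200
    n_x_chondro: int = 6           # pan-type enhancers on chrX
    n_genes: int = 160
    frac_protein_coding: float = 0.9
    frac_chondrogenic: float = 0.35
    gene_spec_fracs: tuple[float, float, float] = (0.84, 0.09, 0.07)
    frac_neg_marker: float = 0.2
    baseline_cov: float = 0.05
    noise_cv: float = 0.1
    jitter: int = 50
    tf_cofraction: float = 0.40
    tf_inactive_fraction: float = 0.03
    n_gws_loci: int = 120
    pareto_alpha: float = 1.5
    pareto_scale: float = 1e-4
    n_stature_loci: int = 8
    seq_length: int = 500
    motif_rate_target: float = 1.0
    motif_rate_background: float = 0.2
    n_decoy_motifs: int = 20

    def __post_init__(self) -> None:
        for name in (
            "n_pan", "n_limb", "n_trunk", "n_non_chondro", "n_subthreshold",
            "n_inactive", "n_x_chondro", "n_genes", "n_gws_loci",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("frac_protein_coding", "frac_chondrogenic",
                     "frac_neg_marker", "tf_cofraction", "tf_inactive_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.noise_cv < 0 or self.jitter < 0:
            raise ParameterError("noise_cv and jitter must be >= 0")


@dataclass
class SynthBundle:
    """Paths plus ground truth of one generated bundle."""

    outdir: Path
    config: SynthConfig
    sizes: ChromSizes
    truth_regions: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_loci: pd.DataFrame
    manifest: dict

    def truth_intervals(self, classes: Sequence[str]) -> list[GenomicInterval]:
        sel = self.truth_regions[self.truth_regions["klass"].isin(classes)]
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sel.itertuples(index=False)
        ]


# ---------------------------------------------------------------------------
# geometry helpers


def _chrom_names(config: SynthConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chroms)] + ["chrX"]


def _chrom_sizes(config: SynthConfig) -> ChromSizes:
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    sizes["chrX"] = config.chrom_length // 2
    return ChromSizes(sizes)


def _slots_per_tad(tad_length: int) -> int:
    usable = tad_length - 2 * _TAD_MARGIN
    if usable < _SLOT_WIDTH:
        raise ParameterError("tad_length too small for feature slots")
    return usable // _SLOT_WIDTH


@dataclass(frozen=True)
class _Slot:
    chrom: str
    tad_index: int  # global index over all TADs
    start: int      # slot start coordinate

    @property
    def enh_zone(self) -> int:
        return self.start + 2000


def _build_tads_and_slots(
    config: SynthConfig, sizes: ChromSizes
) -> tuple[list[GenomicInterval], dict[int, list[_Slot]], list[int], list[int]]:
    """TAD tiling plus per-TAD slot lists; returns (tads, slots_by_tad,
    autosomal_tad_ids, x_tad_ids)."""
    tads: list[GenomicInterval] = []
    slots_by_tad: dict[int, list[_Slot]] = {}
    autosomal, on_x = [], []
    per_tad = _slots_per_tad(config.tad_length)
    for chrom in _chrom_names(config):
        n_tads = sizes[chrom] // config.tad_length
        for t in range(n_tads):
            tad_start = t * config.tad_length
            gid = len(tads)
            tads.append(
                GenomicInterval(chrom, tad_start, tad_start + config.tad_length)
            )
            slots_by_tad[gid] = [
                _Slot(chrom, gid, tad_start + _TAD_MARGIN + k * _SLOT_WIDTH)
                for k in range(per_tad)
            ]
            (autosomal if sizes.is_autosome(chrom) else on_x).append(gid)
    return tads, slots_by_tad, autosomal, on_x


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(0.0, sigma) - sigma * sigma / 2.0))


# ---------------------------------------------------------------------------
# planted signal design


def _draw_fold_change(rng: np.random.Generator) -> float:
    """Intended EGFP+/EGFP− ratio: 75% clearly above threshold (8-32,
    log-uniform), 25% just above it (4.5-6)."""
    if rng.random() < 0.75:
        return float(np.exp(rng.uniform(np.log(8.0), np.log(32.0))))
    return float(rng.uniform(4.5, 6.0))


def _region_levels(
    klass: str, rng: np.random.Generator, baseline: float
) -> dict[str, float]:
    """Intended noise-free mean H3K27ac coverage per tissue x fraction."""
    p = float(rng.uniform(1.0, 3.0))
    f = _draw_fold_change(rng)
    if klass in ("pan", "x_pan"):
        u = float(rng.uniform(0.75, 1.3))
        return {
            "limb_pos": p, "limb_neg": p / f,
            "trunk_pos": p * u, "trunk_neg": p * u / f,
        }
    if klass == "limb":
        return {
            "limb_pos": p, "limb_neg": p / f,
            "trunk_pos": p / float(rng.uniform(2.5, 6.0)), "trunk_neg": baseline,
        }
    if klass == "trunk":
        return {
            "limb_pos": p / float(rng.uniform(2.5, 6.0)), "limb_neg": baseline,
            "trunk_pos": p, "trunk_neg": p / f,
        }
    if klass == "non_chondro":
        u = float(rng.uniform(0.75, 1.3))
        return {
            "limb_pos": p / f, "limb_neg": p,
            "trunk_pos": p * u / f, "trunk_neg": p * u,
        }
    if klass == "subthreshold":
        q = float(rng.uniform(0.8, 1.2))
        return {
            "limb_pos": q, "limb_neg": q / 2.0,
            "trunk_pos": q, "trunk_neg": q / 2.0,
        }
    # inactive: baseline everywhere
    return {
        "limb_pos": baseline, "limb_neg": baseline,
        "trunk_pos": baseline, "trunk_neg": baseline,
    }


# ---------------------------------------------------------------------------
# generation


def generate(config: SynthConfig, outdir: str | Path) -> SynthBundle:
    """Write a full synthetic bundle to ``outdir``; deterministic per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sizes = _chrom_sizes(config)
    tads, slots_by_tad, auto_tads, x_tads = _build_tads_and_slots(config, sizes)

    # --- designate TAD roles -------------------------------------------------
    shuffled = list(rng.permutation(auto_tads))
    n_geneful = min(25, len(shuffled) // 3)
    n_enh_only = min(30, len(shuffled) // 3)
    geneful = shuffled[:n_geneful]
    enh_only = shuffled[n_geneful:n_geneful + n_enh_only]

    free: dict[int, list[_Slot]] = {g: list(s) for g, s in slots_by_tad.items()}

    def take_slot(tad_id: int) -> _Slot:
        return free[tad_id].pop(0)

    def take_random_slot(tad_ids: Sequence[int]) -> _Slot:
        pool = [g for g in tad_ids if free[g]]
        gid = int(rng.choice(pool))
        return free[gid].pop(int(rng.integers(len(free[gid]))))

    # --- genes ---------------------------------------------------------------
    n_coding = int(round(config.n_genes * config.frac_protein_coding))
    n_chondro_genes = min(int(round(n_coding * config.frac_chondrogenic)),
                          2 * max(len(geneful), 1))
    fr = config.gene_spec_fracs
    n_shared = int(round(n_chondro_genes * fr[0]))
    n_limb_g = int(round(n_chondro_genes * fr[1]))
    n_trunk_g = n_chondro_genes - n_shared - n_limb_g
    spec_labels = (["shared"] * n_shared + ["limb_specific"] * n_limb_g
                   + ["trunk_specific"] * n_trunk_g)
    spec_labels = [spec_labels[i] for i in rng.permutation(len(spec_labels))]

    gene_rows = []

    def place_gene(slot: _Slot, name: str, biotype: str, spec: str | None,
                   neg_marker: bool) -> None:
        gstart = slot.start + 2200 + int(rng.integers(0, 401))
        glen = int(rng.integers(1000, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append(
            {
                "name": name, "chrom": slot.chrom, "start": gstart,
                "end": gstart + glen, "strand": strand, "biotype": biotype,
                "specificity": spec or "", "neg_marker": neg_marker,
                "tad": slot.tad_index,
            }
        )

    gi = 0
    for k, gid in enumerate(geneful):  # two chondrogenic genes per geneful TAD
        for _ in range(2):
            if gi >= n_chondro_genes:
                break
            place_gene(take_slot(gid), f"CG{gi:03d}", "protein_coding",
                       spec_labels[gi], False)
            gi += 1
    n_rest_coding = n_coding - gi
    n_neg = int(round(n_rest_coding * config.frac_neg_marker))
    # filler genes go to background TADs so geneful/enhancer-only TADs keep
    # slot capacity for their forced enhancers
    reserved = set(geneful) | set(enh_only)
    other_tads = [g for g in auto_tads if g not in reserved]
    for j in range(n_rest_coding):
        place_gene(take_random_slot(other_tads), f"PG{j:03d}", "protein_coding",
                   None, j < n_neg)
    for j in range(config.n_genes - n_coding):
        place_gene(take_random_slot(other_tads), f"NC{j:03d}", "lincRNA",
                   None, False)
    truth_genes = pd.DataFrame(gene_rows)

    # --- planted regions -----------------------------------------------------
    region_rows = []

    def place_region(slot: _Slot, klass: str) -> dict:
        start = slot.enh_zone + int(rng.integers(0, 1001))
        length = int(rng.integers(300, 601))
        levels = _region_levels(klass, rng, config.baseline_cov)
        row = {
            "region_id": f"R{len(region_rows):04d}",
            "chrom": slot.chrom, "start": start, "end": start + length,
            "klass": "pan" if klass == "x_pan" else klass,
            "tad": slot.tad_index, "tf_bound": False,
            **{f"cov_{k}": v for k, v in levels.items()},
        }
        row["fc_limb"] = levels["limb_pos"] / max(levels["limb_neg"], 1e-9)
        row["fc_trunk"] = levels["trunk_pos"] / max(levels["trunk_neg"], 1e-9)
        region_rows.append(row)
        return row

    chondro_classes = (
        ["pan"] * config.n_pan + ["limb"] * config.n_limb
        + ["trunk"] * config.n_trunk
    )
    chondro_classes = [chondro_classes[i]
                       for i in rng.permutation(len(chondro_classes))]
    # one chondrogenic enhancer forced into every geneful and enhancer-only TAD
    forced = geneful + enh_only
    for idx, klass in enumerate(chondro_classes):
        if idx < len(forced):
            place_region(take_slot(forced[idx]), klass)
        else:
            pool = geneful * 2 + enh_only  # geneful TADs weighted 2:1
            pool = [g for g in pool if free[g]]
            gid = int(rng.choice(pool))
            place_region(free[gid].pop(int(rng.integers(len(free[gid])))), klass)
    for _ in range(config.n_x_chondro):
        place_region(take_random_slot(x_tads), "x_pan")
    for klass, n in (("non_chondro", config.n_non_chondro),
                     ("subthreshold", config.n_subthreshold),
                     ("inactive", config.n_inactive)):
        for _ in range(n):
            place_region(take_random_slot([g for g in auto_tads if free[g]]),
                         klass)
    truth_regions = pd.DataFrame(region_rows)

    # --- TF peaks ------------------------------------------------------------
    chondro_idx = truth_regions.index[
        truth_regions["klass"].isin(["pan", "limb", "trunk"])
    ].to_numpy()
    inactive_idx = truth_regions.index[
        truth_regions["klass"] == "inactive"
    ].to_numpy()
    n_tf_enh = int(math.floor(config.tf_cofraction * len(chondro_idx)))
    n_tf_inact = int(round(config.tf_inactive_fraction * len(inactive_idx)))
    tf_targets = np.concatenate([
        rng.choice(chondro_idx, size=n_tf_enh, replace=False)
        if n_tf_enh else np.array([], dtype=int),
        rng.choice(inactive_idx, size=n_tf_inact, replace=False)
        if n_tf_inact else np.array([], dtype=int),
    ]).astype(int)
    tf_peaks = []
    for ridx in sorted(tf_targets):
        row = truth_regions.loc[ridx]
        s = int(row["start"]) + int(rng.integers(0, max(1, (int(row["end"]) - int(row["start"])) // 2)))
        tf_peaks.append(GenomicInterval(row["chrom"], s, s + 200))
        truth_regions.loc[ridx, "tf_bound"] = True

    # --- GWS loci ------------------------------------------------------------
    variances = config.pareto_scale * (1.0 + rng.pareto(config.pareto_alpha,
                                                        config.n_gws_loci))
    variances = np.sort(variances)[::-1]
    enh_only_set = set(enh_only)
    chondro_auto = truth_regions[
        truth_regions["klass"].isin(["pan", "limb", "trunk"])
        & (truth_regions["chrom"] != "chrX")
    ]
    # alternate enhancer-only / geneful hosts so chondroEnhTAD enhancers sit
    # under slightly more variance than chondroTAD ones
    in_enh_only = chondro_auto[chondro_auto["tad"].isin(enh_only_set)]
    in_geneful = chondro_auto[~chondro_auto["tad"].isin(enh_only_set)]
    alternating: list[pd.Series] = []
    a, b = list(in_enh_only.itertuples()), list(in_geneful.itertuples())
    for i in range(max(len(a), len(b))):
        if i < len(a):
            alternating.append(a[i])
        if i < len(b):
            alternating.append(b[i])
    non_chondro_rows = list(
        truth_regions[truth_regions["klass"] == "non_chondro"].itertuples()
    )
    inactive_rows = list(
        truth_regions[truth_regions["klass"] == "inactive"].itertuples()
    )
    gene_auto = list(truth_genes.itertuples())

    n_loci = config.n_gws_loci
    n_on_chondro = min(40, n_loci, len(alternating))
    n_on_nonch = min(20, max(0, n_loci - n_on_chondro), len(non_chondro_rows))
    n_on_inact = min(10, max(0, n_loci - n_on_chondro - n_on_nonch),
                     len(inactive_rows))
    n_on_gene = min(30, max(0, n_loci - n_on_chondro - n_on_nonch - n_on_inact),
                    len(gene_auto))
    n_empty = n_loci - n_on_chondro - n_on_nonch - n_on_inact - n_on_gene

    locus_rows = []

    def locus_over(chrom: str, anchor_start: int, tad_id: int, target: str) -> None:
        # snap to the anchor's slot (slot grid is TAD-relative)
        tad_start = tads[tad_id].start
        offset = (anchor_start - tad_start - _TAD_MARGIN) // _SLOT_WIDTH
        slot_start = tad_start + _TAD_MARGIN + offset * _SLOT_WIDTH
        s = slot_start + 1500
        e = slot_start + 4500 + int(rng.integers(0, 401))
        locus_rows.append(
            {
                "locus_id": f"L{len(locus_rows):04d}", "chrom": chrom,
                "start": s, "end": e,
                "variance_explained": float(variances[len(locus_rows)]),
                "planted_over": target,
            }
        )

    for t in alternating[:n_on_chondro]:
        locus_over(t.chrom, int(t.start), int(t.tad), "chondro")
    for t in non_chondro_rows[:n_on_nonch]:
        locus_over(t.chrom, int(t.start), int(t.tad), "non_chondro")
    for t in inactive_rows[:n_on_inact]:
        locus_over(t.chrom, int(t.start), int(t.tad), "inactive")
    for t in gene_auto[:n_on_gene]:
        locus_over(t.chrom, int(t.start), int(t.tad), "gene")
    for _ in range(n_empty):
        slot = take_random_slot([g for g in auto_tads if free[g]])
        locus_over(slot.chrom, slot.enh_zone, slot.tad_index, "empty")
    truth_loci = pd.DataFrame(locus_rows)

    # --- stature loci (named TAD spans) -------------------------------------
    stature_hosts = (geneful[: max(1, config.n_stature_loci - 3)]
                     + enh_only[:3])[: config.n_stature_loci]
    stature = {
        f"LS{k + 1}": tads[gid] for k, gid in enumerate(sorted(stature_hosts))
    }

    # --- write interval/annotation files ------------------------------------
    write_chrom_sizes(sizes, outdir / "chrom.sizes")
    write_bed(tads, outdir / "tads.bed")
    genes = [
        GeneRecord(
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
            r.name, r.biotype,
        )
        for r in truth_genes.itertuples(index=False)
    ]
    write_gene_table(genes, outdir / "genes.tsv")
    with open(outdir / "stature_loci.bed", "w") as fh:
        for name, iv in stature.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    write_bed(tf_peaks, outdir / "tf_peaks.bed")
    truth_loci[["chrom", "start", "end", "variance_explained"]].assign(
        variance_explained=lambda d: d["variance_explained"].map("{:.8g}".format)
    ).to_csv(outdir / "gws_loci.tsv", sep="\t", index=False)

    # --- DE tables -----------------------------------------------------------
    for tissue in TISSUES:
        rows = []
        for r in truth_genes.itertuples(index=False):
            spec = r.specificity
            if spec == "shared" or spec == f"{tissue}_specific":
                lfc, padj = float(rng.uniform(1.8, 4.0)), 0.001
            elif spec:  # chondrogenic but specific to the other tissue
                lfc, padj = float(rng.uniform(-0.5, 0.5)), 0.5
            elif r.neg_marker:
                lfc, padj = float(rng.uniform(-4.0, -1.8)), 0.001
            else:
                lfc, padj = float(rng.uniform(-1.0, 1.0)), float(rng.uniform(0.1, 0.9))
            rows.append({"gene": r.name, "log2FC": round(lfc, 4), "padj": padj})
        pd.DataFrame(rows).to_csv(outdir / f"de_{tissue}.tsv", sep="\t",
                                  index=False)

    # --- ATAC peaks (jittered replicates, all conditions) --------------------
    def jittered(iv_start: int, iv_end: int) -> tuple[int, int]:
        j = config.jitter
        if j == 0:
            return iv_start, iv_end
        return (iv_start + int(rng.integers(-j, j + 1)),
                iv_end + int(rng.integers(-j, j + 1)))

    for tissue in TISSUES:
        for fraction in FRACTIONS:
            for rep in (1, 2):
                peaks = []
                for r in truth_regions.itertuples(index=False):
                    s, e = jittered(int(r.start), int(r.end))
                    peaks.append(GenomicInterval(r.chrom, s, e))
                intervals_to_narrowpeak(
                    peaks,
                    outdir / f"atac_{tissue}_{fraction}_rep{rep}.narrowPeak",
                    signal=[5.0] * len(peaks),
                )

    # --- H3K27ac candidate peaks per tissue ----------------------------------
    active = truth_regions[truth_regions["klass"] != "inactive"]
    for tissue in TISSUES:
        ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
               for r in active.itertuples(index=False)]
        intervals_to_narrowpeak(
            ivs, outdir / f"h3k27ac_{tissue}_peaks.narrowPeak",
            signal=[10.0] * len(ivs),
        )

    # --- H3K27ac coverage tracks ---------------------------------------------
    for tissue in TISSUES:
        for fraction in FRACTIONS:
            cond = f"{tissue}_{fraction}"
            segs: dict[str, list[tuple[int, int, float]]] = {c: [] for c in sizes}
            for r in truth_regions.itertuples(index=False):
                level = getattr(r, f"cov_{cond}")
                noisy = level * _lognormal_factor(rng, config.noise_cv)
                segs[r.chrom].append((int(r.start), int(r.end), float(noisy)))
            track_segs = {}
            for chrom in sizes:
                parts = sorted(segs[chrom])
                starts, ends, values = [], [], []
                cursor = 0
                for s, e, v in parts:
                    if s > cursor:
                        starts.append(cursor); ends.append(s)
                        values.append(config.baseline_cov)
                    starts.append(s); ends.append(e); values.append(v)
                    cursor = e
                if cursor < sizes[chrom]:
                    starts.append(cursor); ends.append(sizes[chrom])
                    values.append(config.baseline_cov)
                track_segs[chrom] = (
                    np.array(starts, dtype=np.int64),
                    np.array(ends, dtype=np.int64),
                    np.array(values, dtype=float),
                )
            CoverageTrack(sizes, track_segs, f"{cond}_H3K27ac").to_bedgraph(
                outdir / f"h3k27ac_{cond}.bedGraph"
            )

    # --- sequences and motifs ------------------------------------------------
    motif = PositionCountMatrix(
        "SOX_SYNTH",
        np.array(
            # A    C    G    T   per column of consensus CATTGTTC
            [[2, 94, 2, 2],
             [94, 2, 2, 2],
             [2, 2, 2, 94],
             [2, 2, 2, 94],
             [2, 2, 94, 2],
             [2, 2, 2, 94],
             [2, 2, 2, 94],
             [2, 94, 2, 2]], dtype=float
        ).T,
    )
    decoys = []
    for d in range(config.n_decoy_motifs):
        cons = rng.integers(0, 4, size=8)
        counts = np.full((4, 8), 2.0)
        counts[cons, np.arange(8)] = 94.0
        decoys.append(PositionCountMatrix(f"DECOY_{d:02d}", counts))
    write_pcms([motif] + decoys, outdir / "motifs.pcm")

    def random_seq(n: int) -> list[str]:
        return ["ACGT"[i] for i in rng.integers(0, 4, size=n)]

    def plant(seq: list[str], rate: float) -> None:
        n_occ = int(rng.poisson(rate))
        cons = motif.consensus()
        for _ in range(n_occ):
            pos = int(rng.integers(0, len(seq) - len(cons) + 1))
            site = cons if rng.random() < 0.5 else reverse_complement(cons)
            seq[pos:pos + len(cons)] = list(site)

    with open(outdir / "sequences_target.fa", "w") as ft:
        for r in truth_regions[
            truth_regions["klass"].isin(["pan", "limb", "trunk"])
        ].itertuples(index=False):
            seq = random_seq(config.seq_length)
            plant(seq, config.motif_rate_target)
            ft.write(f">{r.region_id}\n{''.join(seq)}\n")
    with open(outdir / "sequences_background.fa", "w") as fb:
        for r in truth_regions[
            truth_regions["klass"] == "inactive"
        ].itertuples(index=False):
            seq = random_seq(config.seq_length)
            plant(seq, config.motif_rate_background)
            fb.write(f">{r.region_id}\n{''.join(seq)}\n")

    # --- truth tables and manifest -------------------------------------------
    truth_regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth_loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "chrom_sizes": "chrom.sizes",
        "tads": "tads.bed",
        "genes": "genes.tsv",
        "de_tables": {t: f"de_{t}.tsv" for t in TISSUES},
        "atac": {
            t: {f: [f"atac_{t}_{f}_rep{r}.narrowPeak" for r in (1, 2)]
                for f in FRACTIONS}
            for t in TISSUES
        },
        "h3k27ac_peaks": {t: f"h3k27ac_{t}_peaks.narrowPeak" for t in TISSUES},
        "h3k27ac_coverage": {
            t: {f: f"h3k27ac_{t}_{f}.bedGraph" for f in FRACTIONS}
            for t in TISSUES
        },
        "tf_peaks": "tf_peaks.bed",
        "gws_loci": "gws_loci.tsv",
        "stature_loci": "stature_loci.bed",
        "sequences": {
            "target": "sequences_target.fa",
            "background": "sequences_background.fa",
        },
        "motifs": "motifs.pcm",
        "truth": {
            "regions": "truth_regions.tsv",
            "genes": "truth_genes.tsv",
            "loci": "truth_loci.tsv",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return SynthBundle(outdir, config, sizes, truth_regions, truth_genes,
                       truth_loci, manifest)


# ---------------------------------------------------------------------------
# validation


def validate_bundle(outdir: str | Path) -> dict:
    """Re-parse a generated bundle and check its internal invariants.

    Returns a report dict with a (possibly empty) list of violations; it never
    raises for content problems, only records them.
    """
    outdir = Path(outdir)
    violations: list[str] = []
    checked = 0

    def check(cond: bool, msg: str) -> None:
        nonlocal checked
        checked += 1
        if not cond:
            violations.append(msg)

    try:
        from .formats import read_bedgraph, read_chrom_sizes

        sizes = read_chrom_sizes(outdir / "chrom.sizes")
        manifest = json.loads((outdir / "manifest.json").read_text())
        truth = pd.read_csv(outdir / "truth_regions.tsv", sep="\t")
        # truth coordinates on-chromosome, planted regions non-overlapping
        for chrom, grp in truth.groupby("chrom"):
            check(chrom in sizes, f"unknown chromosome {chrom} in truth")
            if chrom in sizes:
                check(bool((grp["end"] <= sizes[chrom]).all()),
                      f"truth region beyond {chrom} end")
            grp = grp.sort_values("start")
            overlaps = (grp["start"].to_numpy()[1:]
                        < grp["end"].to_numpy()[:-1])
            check(not overlaps.any(), f"overlapping planted regions on {chrom}")
        # coverage files parse (read_bedgraph enforces its own invariants)
        for tissue in TISSUES:
            for fraction in FRACTIONS:
                try:
                    read_bedgraph(
                        outdir / f"h3k27ac_{tissue}_{fraction}.bedGraph", sizes
                    )
                    check(True, "")
                except Exception as exc:  # recorded, not raised
                    check(False, f"bedGraph {tissue}_{fraction}: {exc}")
        # FASTA parses and sequence counts match the truth table
        n_chondro = int(truth["klass"].isin(["pan", "limb", "trunk"]).sum())
        try:
            target = read_fasta(outdir / "sequences_target.fa")
            check(len(target) == n_chondro,
                  f"target FASTA has {len(target)} sequences, expected {n_chondro}")
        except Exception as exc:
            check(False, f"target FASTA: {exc}")
        try:
            read_pcms(outdir / "motifs.pcm")
            check(True, "")
        except Exception as exc:
            check(False, f"PCM file: {exc}")
        check("config" in manifest, "manifest lacks config")
    except FileNotFoundError as exc:
        violations.append(f"missing file: {exc}")
    return {"violations": violations, "n_checks": checked}
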