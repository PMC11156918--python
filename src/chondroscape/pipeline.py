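"""End-to-end orchestration: from an input bundle to the landscape report.

``run_all`` executes enhancer calling for both tissues, cross-tissue
classification, TAD categorization, TF-binding and stature-locus overlap
counting, height-variance attribution, and (optionally) motif enrichment,
writing per-stage outputs plus a deterministic ``summary.json``. Every stage
is a pure function of the inputs and parameters; the only randomness in the
package lives in the synthetic-data generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import enhancers as enh
from . import heightvar as hv
from . import motifs as mo
from . import overlaps as ov
from . import tads as td
from .formats import (
    quantify,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_gene_table,
    read_narrowpeak,
    write_bed,
)
from .intervals import (
    ChromSizes,
    GeneRecord,
    GenomicInterval,
    merge_within,
    overlaps_any,
    promoter_windows,
)

log = logging.getLogger("chondroscape")

__all__ = ["PipelineConfig", "StageError", "run_all", "load_bundle_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


@dataclass
class PipelineConfig:
    """Paths to every input plus analysis parameters."""

    chrom_sizes: Path
    tads: Path
    genes: Path
    de_tables: Mapping[str, Path]                 # tissue -> TSV
    atac: Mapping[str, Sequence[Path]]            # tissue -> [rep1, rep2] (EGFP+)
    h3k27ac_peaks: Mapping[str, Path]             # tissue -> narrowPeak
    h3k27ac_coverage: Mapping[str, Mapping[str, Path]]  # tissue -> fraction -> bedGraph
    tf_peaks: Path | None = None
    gws_loci: Path | None = None
    stature_loci: Path | None = None
    sequences_target: Path | None = None
    sequences_background: Path | None = None
    motifs: Path | None = None
    params: enh.CallingParams = field(default_factory=enh.CallingParams)
    top_k: int = 877
    ranking_metric: str = "fold_change"
    motif_alpha: float = 0.001

    def validate(self) -> None:
        """Check the inputs the preamble reads; stage-specific files are
        checked (and reported) by their own stage."""
        required = [self.chrom_sizes, self.genes, *self.de_tables.values()]
        for per_tissue in self.h3k27ac_coverage.values():
            required.extend(per_tissue.values())
        for p in required:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def load_bundle_config(bundle_dir: str | Path, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a generated bundle's manifest."""
    bundle_dir = Path(bundle_dir)
    man = json.loads((bundle_dir / "manifest.json").read_text())

    def p(rel: str | None) -> Path | None:
        return bundle_dir / rel if rel else None

    return PipelineConfig(
        chrom_sizes=p(man["chrom_sizes"]),
        tads=p(man["tads"]),
        genes=p(man["genes"]),
        de_tables={t: p(v) for t, v in man["de_tables"].items()},
        atac={t: [p(r) for r in v["pos"]] for t, v in man["atac"].items()},
        h3k27ac_peaks={t: p(v) for t, v in man["h3k27ac_peaks"].items()},
        h3k27ac_coverage={
            t: {f: p(v) for f, v in per.items()}
            for t, per in man["h3k27ac_coverage"].items()
        },
        tf_peaks=p(man.get("tf_peaks")),
        gws_loci=p(man.get("gws_loci")),
        stature_loci=p(man.get("stature_loci")),
        sequences_target=p(man.get("sequences", {}).get("target")),
        sequences_background=p(man.get("sequences", {}).get("background")),
        motifs=p(man.get("motifs")),
        **overrides,
    )


def _round_floats(obj):
    """Round every float to 8 decimals so summary JSON is byte-stable."""
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 8)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("enhancers")
def _call_enhancers(config: PipelineConfig, sizes: ChromSizes,
                    genes: list[GeneRecord], tracks) -> dict:
    params = config.params
    promoters = promoter_windows(
        genes, params.promoter_up, params.promoter_down, sizes
    )
    per_tissue_calls: dict[str, list[enh.EnhancerCall]] = {}
    consensus_by_tissue: dict[str, list[GenomicInterval]] = {}
    for tissue, reps in config.atac.items():
        rep_peaks = [read_narrowpeak(r, sizes)[0] for r in reps]
        consensus = enh.consensus_atac(rep_peaks[0], rep_peaks[1], sizes, params)
        consensus_by_tissue[tissue] = consensus
        k27_peaks, _ = read_narrowpeak(config.h3k27ac_peaks[tissue], sizes)
        candidates = enh.candidate_regions(k27_peaks, consensus, promoters)
        cov_pos = quantify(candidates, tracks[tissue]["pos"])
        cov_neg = quantify(candidates, tracks[tissue]["neg"])
        per_tissue_calls[tissue] = enh.call_differential(
            candidates, cov_pos, cov_neg, params, tissue
        )
    aggregated = enh.classify_tissue(
        per_tissue_calls.get("limb", []),
        per_tissue_calls.get("trunk", []),
        tracks["limb"]["pos"], tracks["trunk"]["pos"], params,
        tracks["limb"]["neg"], tracks["trunk"]["neg"],
    )
    non_chondro = merge_within(
        [c.interval for calls in per_tissue_calls.values() for c in calls
         if c.activity == enh.NON_CHONDROGENIC],
        max_gap=0,
    )
    return {
        "per_tissue_calls": per_tissue_calls,
        "consensus": consensus_by_tissue,
        "aggregated": aggregated,
        "non_chondro": non_chondro,
    }


@_stage("tads")
def _categorize_tads(config: PipelineConfig, sizes: ChromSizes,
                     aggregated, chondro_genes) -> dict:
    tad_ivs = read_bed(config.tads, sizes)
    assignments, unassigned = td.assign_enhancers(
        [a.interval for a in aggregated], tad_ivs
    )
    records = td.categorize(tad_ivs, assignments, chondro_genes)
    stats = td.per_tad_stats(records)
    x = [r.n_enhancers for r in records if r.category == td.CHONDRO_TAD]
    y = [r.n_enhancers for r in records if r.category == td.CHONDRO_ENH_TAD]
    test = td.rank_sum_test(x, y) if x and y else (float("nan"), float("nan"))
    return {
        "records": records,
        "assignments": assignments,
        "unassigned": unassigned,
        "stats": stats,
        "rank_sum": {"U": test[0], "p": test[1]},
    }


@_stage("overlaps")
def _overlap_stage(config: PipelineConfig, sizes: ChromSizes, called) -> dict:
    out: dict = {}
    aggregated = called["aggregated"]
    # inactive control: accessible consensus regions without any H3K27ac peak
    accessible = merge_within(
        [iv for cons in called["consensus"].values() for iv in cons], max_gap=0
    )
    k27_all = []
    for tissue in config.h3k27ac_peaks:
        k27_all.extend(read_narrowpeak(config.h3k27ac_peaks[tissue], sizes)[0])
    inactive = [
        iv for iv, hit in zip(accessible, overlaps_any(accessible, k27_all))
        if not hit
    ] if accessible else []
    control = ov.prepare_control(inactive)
    out["n_inactive_control"] = len(control)
    if config.tf_peaks and aggregated:
        tf = merge_within(read_bed(config.tf_peaks, sizes), 500)
        query = [a.interval for a in aggregated
                 if a.tissue_class in ("limb_enriched", "pan")]
        if query:
            report = ov.tf_overlap(query, tf, control)
            out["tf"] = dict(report.__dict__)
    if config.stature_loci:
        loci_df = pd.read_csv(
            config.stature_loci, sep="\t", header=None,
            names=["chrom", "start", "end", "name"],
        )
        loci = {
            str(r.name): GenomicInterval(sizes.normalize(r.chrom),
                                         int(r.start), int(r.end))
            for r in loci_df.itertuples(index=False)
        }
        out["stature"] = ov.locus_overlap_counts(
            loci, [a.interval for a in aggregated], called["non_chondro"],
            called["chondro_genes"],
        )
    out["_control"] = control
    return out


@_stage("heightvar")
def _heightvar_stage(config: PipelineConfig, sizes: ChromSizes, called,
                     tad_result, genes) -> dict:
    loci = hv.read_gws_loci(config.gws_loci, sizes)
    coding, non_coding = hv.split_coding(loci, genes)
    aggregated = called["aggregated"]
    records = tad_result["records"]
    in_chondro_tad: set[int] = set()
    in_enh_tad: set[int] = set()
    for rec in records:
        target = (in_chondro_tad if rec.category == td.CHONDRO_TAD
                  else in_enh_tad if rec.category == td.CHONDRO_ENH_TAD
                  else None)
        if target is not None:
            target.update(rec.enhancer_ids)
    sets = {
        "chondroTAD_enhancers": [aggregated[i] for i in sorted(in_chondro_tad)],
        "chondroEnhTAD_enhancers": [aggregated[i] for i in sorted(in_enh_tad)],
        "non_chondrogenic": called["non_chondro"],
    }
    k = min([config.top_k] + [len(v) for v in sets.values() if len(v)])
    matched = {}
    for name, enh_set in sets.items():
        if name == "non_chondrogenic":
            # non-chondrogenic calls carry no per-tissue fold change; the
            # size-matched subset is the autosomal set truncated to k
            auto = [iv for iv in enh_set if sizes.is_autosome(iv.chrom)]
            matched[name] = auto[:k]
        else:
            matched[name] = hv.top_k_enhancers(
                enh_set, k, sizes, config.ranking_metric
            )
    table = hv.compare_sets(non_coding, matched)
    curves = [
        hv.cumulative_curve(non_coding, matched[name], label=name)[0]
        for name in matched
    ]
    return {
        "n_loci": len(loci),
        "n_coding": len(coding),
        "n_non_coding": len(non_coding),
        "k_matched": k,
        "per_set": {
            name: {c: table.loc[name, c] for c in table.columns}
            for name in table.index
        },
        "_curves": curves,
    }


@_stage("motifs")
def _motif_stage(config: PipelineConfig) -> dict:
    target = list(mo.read_fasta(config.sequences_target).values())
    background = list(mo.read_fasta(config.sequences_background).values())
    pcms = mo.read_pcms(config.motifs)
    table = mo.enrich_all(target, background, pcms, config.motif_alpha)
    top = table.iloc[0]
    return {
        "n_motifs": len(table),
        "top_motif": str(top["motif"]),
        "top_log2_fold_change": float(top["log2_fold_change"]),
        "_table": table,
    }


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write per-stage outputs plus ``summary.json``.

    Returns the summary dict. Any stage failure raises :class:`StageError`
    naming the stage; a machine-readable error record is written to
    ``error.json`` in that case.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        try:
            config.validate()
            sizes = read_chrom_sizes(config.chrom_sizes)
            genes = read_gene_table(config.genes, sizes)
            de_tables = {
                t: pd.read_csv(path, sep="\t")
                for t, path in config.de_tables.items()
            }
            gene_classes = enh.classify_genes(de_tables)
            chondro_names = {g.gene for g in gene_classes if g.is_chondrogenic}
            chondro_genes = [g for g in genes if g.name in chondro_names]

            tracks = {
                tissue: {
                    fraction: read_bedgraph(path, sizes, f"{tissue}_{fraction}")
                    for fraction, path in per.items()
                }
                for tissue, per in config.h3k27ac_coverage.items()
            }
        except Exception as exc:
            raise StageError("inputs", str(exc)) from exc
        called = _call_enhancers(config, sizes, genes, tracks)
        called["chondro_genes"] = chondro_genes
        aggregated = called["aggregated"]

        summary: dict = {
            "landscape": enh.summarize_landscape(
                aggregated, called["per_tissue_calls"], gene_classes,
                called["non_chondro"],
            )
        }

        tad_result = _categorize_tads(config, sizes, aggregated, chondro_genes)
        summary["tads"] = {
            "per_category": tad_result["stats"],
            "n_assigned": sum(len(v) for v in tad_result["assignments"].values()),
            "n_unassigned": len(tad_result["unassigned"]),
            "rank_sum": tad_result["rank_sum"],
        }

        overlap_out = _overlap_stage(config, sizes, called)
        control = overlap_out.pop("_control")
        summary["overlaps"] = overlap_out

        if config.gws_loci:
            hv_out = _heightvar_stage(config, sizes, called, tad_result, genes)
            curves = hv_out.pop("_curves")
            summary["heightvar"] = hv_out
            curve_df = pd.concat(
                [
                    pd.DataFrame({"set": c.label, "x": c.x, "y": c.y})
                    for c in curves
                ],
                ignore_index=True,
            )
            curve_df.to_csv(out_dir / "variance_curves.tsv", sep="\t",
                            index=False, float_format="%.8g")

        if config.motifs and config.sequences_target and config.sequences_background:
            motif_out = _motif_stage(config)
            motif_out.pop("_table").to_csv(
                out_dir / "motif_enrichment.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            summary["motifs"] = motif_out

        # per-stage interval outputs
        write_bed(
            [a.interval for a in aggregated], out_dir / "chondrogenic_enhancers.bed",
            names=[f"{a.tissue_class}_{i}" for i, a in enumerate(aggregated)],
        )
        write_bed(called["non_chondro"], out_dir / "non_chondrogenic_enhancers.bed")
        write_bed(control, out_dir / "inactive_control.bed")
        pd.DataFrame(
            [
                {
                    "chrom": r.interval.chrom, "start": r.interval.start,
                    "end": r.interval.end, "category": r.category,
                    "n_enhancers": r.n_enhancers,
                    "genes": ",".join(r.chondro_gene_names),
                }
                for r in tad_result["records"]
            ]
        ).to_csv(out_dir / "tads.tsv", sep="\t", index=False)

        summary = _round_floats(summary)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except StageError as err:
        with open(out_dir / "error.json", "w") as fh:
            json.dump(err.record, fh, indent=2)
        raise
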