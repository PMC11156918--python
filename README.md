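# chondroscape

Toolkit for mapping the **chondrogenic enhancer landscape** from
sorted-population epigenomic data, and for connecting that landscape to
skeletal phenotypes.

The study design it supports: fetal mouse limb and trunk tissues carrying a
*Col2a1* fluorescent regulatory sensor are FACS-sorted into chondrocyte
(EGFP+) and non-chondrocyte (EGFP−) fractions, and each fraction is profiled
by ATAC-seq (two replicates) and H3K27ac ChIP-seq. Starting from peak calls
and normalized coverage tracks — not reads — the package:

1. **calls differential enhancers** per tissue: reproducible EGFP+ ATAC peaks
   (present in both replicates, extended ±150 bp) are intersected with
   H3K27ac peaks, promoter windows (−2 kb/+500 b around protein-coding TSSs)
   are excluded, and a candidate is *chondrogenic* iff

   cov⁺ ≥ 0.5 and cov⁺ / cov⁻ ≥ 4

   (mirrored for *non-chondrogenic*), with surviving calls merged within
   500 bp;
2. **classifies tissue specificity** of chondrogenic enhancers
   (limb-enriched / trunk-enriched / *pan*-chondrogenic at a 2-fold H3K27ac
   ratio between tissues) and marker genes (|log2FC| > 1.5, BH-adjusted
   p < 0.05);
3. **categorizes TADs** as *chondroTADs* (≥1 chondrogenic enhancer and ≥1
   protein-coding chondrogenic gene) vs *chondroEnhTADs* (enhancers only),
   with per-TAD enhancer statistics and a two-tailed Wilcoxon rank-sum test;
4. **counts TF-binding overlap** (e.g. SOX9 ChIP peaks) against a merged
   inactive-chromatin control, and enhancer content of large named loci;
5. **attributes height variance**: GWS height loci are split by
   protein-coding overlap, enhancer sets are size-matched (top-877 autosomal
   by between-fraction fold change), and a cumulative curve accumulates each
   locus's variance on x and, on y, only the variance of loci overlapped by
   the set;
6. **scores motif enrichment** of enhancer vs inactive sequences with
   exactly calibrated log-odds hit thresholds (P(hit) ≤ α per background
   k-mer) and a pseudocounted log2 hit-rate ratio.

A first-class **synthetic-data generator** (`chondroscape.synth`) emits a
complete, internally consistent input bundle — jittered replicate peaks,
noisy coverage, TADs, DE tables, TF peaks, GWS loci, sequences and motifs —
with a ground-truth table for every planted feature, so the whole pipeline is
testable end to end.

## Worked example

```bash
chondroscape synth generate --seed 42 --out bundle/
chondroscape run-all --bundle bundle/ --out results/
python -c "import json; s=json.load(open('results/summary.json')); \
           print(json.dumps(s['landscape'], indent=1))"
```

prints (seed 42, default study conditions):

```
{
 "n_chondrogenic": 106,
 "tissue_class_counts": {"limb_enriched": 18, "trunk_enriched": 8, "pan": 80},
 "tissue_class_pct": {"limb_enriched": 17, "trunk_enriched": 8, "pan": 75},
 "n_non_chondrogenic": 33,
 "n_total": 139,
 "pct_chondrogenic_of_total": 76,
 ...
}
```

i.e. 106 chondrogenic enhancers were called, 75% of them active in both
tissues (*pan*-chondrogenic), 17%/8% enriched in limb/trunk chondrocytes, and
76% of all differential regions had the stronger signal in the chondrocyte
fraction. The same `summary.json` reports the TAD categories (here 25
chondroTADs averaging 2.2 enhancers vs 35 chondroEnhTADs averaging 1.5,
rank-sum p ≈ 6e-3), the TF-overlap report (40% of limb-enriched + pan
enhancers bound vs 3.0% of inactive regions — the planted co-binding
fractions), and the height-variance table, in which both chondrogenic
enhancer sets explain more cumulative variance than the size-matched
non-chondrogenic set. `results/variance_curves.tsv` holds the cumulative
curves and `results/motif_enrichment.tsv` the motif table (the planted motif
ranks first).

Every stage is also importable directly; see the API in
`chondroscape/enhancers.py`, `tads.py`, `overlaps.py`, `heightvar.py`,
`motifs.py`, and the model documentation in `docs/methods.md`.

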