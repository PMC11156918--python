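# Methods

## The calling model

The package treats enhancer discovery as a deterministic decision rule on
region-level signal, not as a fitted statistical model. For one tissue, with
EGFP+ (chondrocyte) and EGFP− (remaining cells) sorted fractions:

1. **Accessible consensus.** ATAC peaks reproducible across the two
   replicates are kept: a peak survives iff it overlaps (≥1 bp) a peak of the
   other replicate; surviving peaks from both replicates are unioned and
   merged, then extended by `atac_flank` (150 bp) per side. The union (rather
   than the rep-1 footprint) is used so the operation is symmetric under
   replicate relabelling.
2. **Candidates.** H3K27ac peaks of the tissue that overlap the accessible
   consensus and do not touch any promoter window. Promoter windows are
   strand-aware: 2 000 bp upstream of each protein-coding TSS through 500 bp
   downstream (the 500 counts the TSS base itself). A candidate keeps its
   H3K27ac peak footprint; the intersection acts as a filter, not a clip.
3. **Differential call.** With mean normalized H3K27ac coverage cov⁺/cov⁻
   over the candidate: *chondrogenic* iff cov⁺ ≥ `min_pos_cov` (0.5 signal
   units) **and** cov⁺/max(cov⁻, pc) ≥ `fc_threshold` (4); the
   *non-chondrogenic* rule mirrors the fractions. Thresholds are inclusive
   (≥). The pseudocount pc (0.01 signal units) only floors denominators; the
   0.5 numerator floor is what prevents spurious calls at near-zero signal.
   Surviving calls of each class are merged within `merge_gap` (500 bp)
   separately; a merged call carries the per-fraction **maximum** over its
   members and a fold change recomputed from those maxima — a deterministic,
   order-independent convention.
4. **Tissue class.** Chondrogenic calls from limb and trunk are aggregated
   (overlap-merged). Per aggregated region, mean EGFP+ H3K27ac coverage is
   compared between tissues: limb-enriched iff limb/trunk ≥ `tissue_fc` (2),
   trunk-enriched by the mirror, else *pan*-chondrogenic; denominators are
   floored at pc.

Marker genes come from per-tissue differential-expression tables (EGFP+ vs
EGFP−): a gene is an EGFP+ marker iff log2FC > 1.5 and BH-adjusted p < 0.05
(strict inequalities; a gene sitting exactly on 1.5 is not a marker), with
the mirrored rule for EGFP− markers; EGFP+ markers partition into
limb-specific / trunk-specific / shared across tissues.

## TAD bookkeeping and the rank-sum test

TADs are inputs (BED3) and must be disjoint. An enhancer is assigned iff it
overlaps **exactly one** TAD; boundary-straddling or inter-TAD enhancers are
reported unassigned — this is what makes "unambiguously assigned" a
meaningful count. Genes attach to TADs by any body overlap, so a
boundary-spanning gene can belong to two TADs. A TAD with ≥1 chondrogenic
enhancer is a *chondroTAD* if it also holds ≥1 protein-coding chondrogenic
gene, else a *chondroEnhTAD*; both categories require ≥1 enhancer by
construction, so zero-enhancer TADs never enter either distribution.

Per-TAD enhancer counts are compared with a two-tailed Wilcoxon rank-sum
test. For min(n) ≤ 8 the exact null distribution is computed by a dynamic
program over (doubled, hence integral) midrank sums — equivalent to
enumerating all label assignments, but polynomial, and correct under ties.
Larger samples use the tie-corrected normal approximation
(`scipy.stats.mannwhitneyu`). The two branches agree to within a few percent
relative p at moderate sample sizes outside the deep tail; exact tail
probabilities below ~0.02 deviate from the continuity-corrected normal by
more than 10%, which is inherent to the approximation, not a defect of
either branch.

## Overlap counting

All overlap questions use a 1 bp any-overlap threshold on half-open
coordinates (abutting intervals never overlap). The TF-binding control set is
the accessible consensus stripped of every region touching an H3K27ac peak in
any condition, merged within 500 bp — the same construction as the query's
universe, so the two fractions are comparable. Query fractions are reported
as integer percent, control fractions to one decimal, matching the precision
such counts are conventionally reported at. In named-locus counting an
enhancer inside two overlapping loci is counted once in the totals
(deduplication by identity, not footprint).

## Height-variance attribution

GWS loci are non-overlapping genomic segments, each weighted by the fraction
of height variance its significant variants explain. Loci are split into
protein-coding vs non-coding by any-overlap with protein-coding gene bodies.
Enhancer sets are size-matched before comparison: autosomal enhancers ranked
by the maximum over tissues of the EGFP+/EGFP− fold change, top k = 877 kept
(ties broken by coordinates; sets smaller than k are used whole and
flagged). A `coverage_diff` ranking (max between-fraction coverage
difference) is available behind a switch for sensitivity analysis; fold
change is the default because the matched quantity is an enrichment, not an
absolute difference. The cumulative curve walks loci from highest to lowest
variance: x accumulates every locus, y accumulates a locus iff ≥1 enhancer of
the set overlaps it. A locus's variance is counted once however many
enhancers overlap it — attribution is locus-level; per-enhancer attribution
would double-count and break y ≤ x.

## Motif enrichment

Position count matrices (HOCOMOCO plain-text layout) are converted to log2
odds with a 0.8 per-cell pseudocount under a zero-order background (default:
the base composition of the background sequence set). The hit threshold per
motif is the smallest score t with P(score ≥ t) ≤ α (default 0.001) for a
random background k-mer, computed exactly by convolving per-position score
distributions on a 0.01-bit lattice; scanning uses the same lattice, so
calibration and counting agree exactly. Degenerate motifs whose whole score
distribution sits at one value get an unattainable threshold and zero hits.
Both strands are scanned; windows containing N are excluded from both hits
and scannable positions; overlapping hits are not collapsed. Enrichment is
log2(((h_t+0.5)/p_t) / ((h_b+0.5)/p_b)).

This is a deliberate simplification of the analysis style common for such
data (order-1 Markov background, compound-Poisson enrichment test): it
reproduces the *ranking* behaviour at desk scale, and its absolute
enrichment values are not comparable to values produced by the richer test.

## The synthetic-data generator

The generator emulates the sorted-population study: two tissues × two
fractions, replicated ATAC peaks, H3K27ac coverage with planted fold
changes, and all downstream annotation layers. Design choices:

- **Geometry.** TADs tile each chromosome (50 kb). Features occupy private
  6 kb slots keeping 2 kb clear of TAD boundaries; enhancers sit in a zone
  of their slot that promoter windows from neighbouring slots provably
  cannot reach, and far enough apart that consensus extension (±150 bp) plus
  the 500 bp call merge can never bridge two planted features. This makes
  ground truth exactly recoverable at zero noise.
- **Classes and proportions.** Planted chondrogenic enhancers default to
  74/18/8 pan/limb/trunk (the landscape's class shares), 33 non-chondrogenic
  (≈25% of all differential regions), 20 sub-threshold regions planted at
  fold change 2 (negative controls for the ≥4 rule), 200 accessible-but-
  inactive regions, and 6 pan-type enhancers on chrX to exercise the
  autosome filter. Gene specificity defaults to 84/9/7
  shared/limb/trunk (the marker-gene split).
- **Signal.** Coverage is a flat 0.05 baseline with planted regions at
  levels implying the intended fold change: enriched-fraction levels are
  drawn uniform(1.0, 3.0); 75% of intended fold changes are drawn
  log-uniform in [8, 32] (clearly above threshold) and 25% uniform in
  [4.5, 6] (just above). Noise is multiplicative log-normal, mean 1, with
  CV `noise_cv` (default 0.1) per region × condition — the simplest
  positivity-preserving model for region-level coverage. ATAC replicate peak
  edges jitter uniformly within ±`jitter` bp (default 50).
- **DE tables** are written directly with marker log2FCs at least 0.3 beyond
  the 1.5 threshold and padj 0.001 (markers) or ≥ 0.1 (non-markers), rather
  than simulating counts and fitting a DE model — model fitting is not part
  of this package's scope.
- **Annotation layers.** TF peaks are planted inside 40% of chondrogenic
  enhancers and 3% of inactive regions. GWS-locus variances are Pareto
  (tail index 1.5, scale 1e-4) — heavy-tailed like real per-locus variance
  weights — and high-variance loci are planted over chondrogenic enhancer
  slots (alternating chondroEnhTAD/chondroTAD hosts), middling ones over
  non-chondrogenic and inactive regions, others over genes (making them
  protein-coding) or empty slots. Target FASTA sequences carry the planted
  motif at 1 expected occurrence per 500 bp vs 0.2 in background (5×).
- The candidate H3K27ac peak file per tissue covers every planted region
  with elevated H3K27ac in either fraction, so the mirrored
  (non-chondrogenic) rule operates on the same candidate universe as the
  chondrogenic rule.

What the generator does **not** emulate: read-level sampling noise and peak-
caller artefacts, signal dilution from cell-type heterogeneity in the EGFP−
fraction, correlated noise between fractions, irregular TAD sizes and nested
domains, LD structure among GWS loci, and higher-order sequence composition.
Passing the planted-truth tests therefore demonstrates the correctness of
the decision rules and bookkeeping under the stated noise model — not
calling performance on real chromatin data.

## Problem sizes and numerical conventions

The default bundle (≈360 planted regions, 160 genes, 135 TADs, 120 loci,
21 motifs on a 6.75 Mb genome) was chosen so a full pipeline run takes
seconds while every stage still has non-trivial occupancy; all tests and the
acceptance script run at this scale. Coordinates are 0-based half-open
throughout; chromosome-name dialects are normalized at load. Coverage values
serialize with 6 significant digits (in-memory comparisons at rtol 1e-9,
post-round-trip at 1e-5). Summary JSON floats are rounded to 8 decimals and
keys sorted, so reruns are byte-identical. Merged intervals are unstranded
and carry the maximum member score. All analysis stages are deterministic;
the generator's randomness flows from a single integer seed.

## Known limitations

- The calling rule is threshold-based; no uncertainty accompanies a call,
  and near-threshold behaviour is sensitive to the normalization of the
  input tracks (the package accepts pre-normalized tracks and records any
  factor it applies, but cannot reconstruct the original normalization
  constant without reads).
- Enhancer–gene association is TAD-colocalization only; no contact
  frequency, distance weighting, or expression correlation.
- The motif stage's zero-order background overstates enrichment of motifs
  resembling genome-wide composition biases relative to an order-1 model.
- Liftover between assemblies is out of scope; all inputs must share one
  assembly.
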