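# Methods

This note documents the models, rules and numerical choices behind
`chromlink`, the assumptions of the synthetic-data generator, and what
the passing tests do and do not establish about real data.

## Coordinate and overlap conventions

All internal coordinates are 0-based half-open (BED-native). GTF gene
records and variant positions, which are 1-based inclusive on disk,
are converted on read (`start = pos − 1`) and back on write, so the
round trip is lossless. Overlap everywhere means ≥ 1 bp shared; a reciprocal-fraction variant
is exposed on the peak diff but off by default, because the upstream
convention the pipeline mirrors is plain `bedtools intersect`.
Chromosome names are matched exactly — no "chr" aliasing — and
unshared names surface as a logged warning plus zero overlaps rather
than silent misses.

Promoters are defined as a strand-aware window around the TSS,
default 2,000 bp upstream and 500 bp downstream of transcription,
clipped at zero. On the − strand the window is mirrored so that it
always contains the TSS: `[tss − down + 1, tss + up + 1)`. The window
is a configuration knob (`promoter_up` / `promoter_down`) because no
single annotation defines it; every promoter-dependent result inherits
the choice.

## Replicate consensus and differential peaks

Consensus uses merge-then-count semantics: candidate regions are the
union-merge of all replicate peaks (strict overlap; book-ended peaks
are not merged), and a region is retained when ≥ *k* replicates have
any peak overlapping it. The retained interval is the merged region,
not an intersection, keeping regions contiguous; the support count is
carried in the score column. The alternative (pairwise intersection)
is isolated behind this one function should a user need it.
Differential peaks label every input interval exactly once: a peak
overlapping the other condition is stable, otherwise lost
(control-only) or gained (treated-only); both sides' stable peaks are
kept so the labels partition the union of inputs.

Activating versus repressive epigenetic changes near genes follow the
sign convention: gained H3K27ac or lost H3K27me3 is activating; gained
H3K27me3 or lost H3K27ac is repressive. Events bin by
peak-midpoint-to-TSS distance with default cutoffs 10 kb / 100 kb /
1 Mb (the binning itself is conventional; the cutoffs are
configurable).

## Enhancer states and the state-count curve

The three-mark truth table — active iff H3K27ac present without
H3K27me3; poised iff H3K4me1 and H3K27me3; primed iff H3K4me1 alone;
inactive otherwise — is resolved by the precedence poised > active >
primed > inactive, so H3K27ac+H3K4me1+H3K27me3 is poised. "Activated"
means a non-active state (primed, poised or inactive) becoming active;
"deactivated" is the reverse. The active call does not require
H3K4me1; the table is overridable in code for schemes that do.

Choosing a chromatin-state count compares each model against the
next-larger one: every state's emission row takes the maximum Pearson
correlation against the larger model's rows, and the model score is
the mean of those maxima. Zero-variance rows contribute correlation 0
with a warning. The selected count is the first model whose successor
adds less than ε = 0.01 mean correlation — the point where the curve
plateaus. The synthetic generator emits nested emission matrices with
a controlled plateau: models at or above the true count contain every
prototype row, and each smaller model is derived from its successor by
rotating rows away from their counterparts at an exact correlation
step of 0.03, with rotation directions chosen to keep the counterpart
the best match. The selection therefore recovers the planted count
exactly for true counts between `k_min + 1` and `k_max − 2`.

## Super-enhancers

Stitching merges CREs whose gaps are ≤ 12,500 bp (the canonical ROSE
default; inclusive threshold), after dropping constituents fully
inside TSS ± 2,500 bp windows. Region signal is the sum of overlapping
H3K27ac peak signals, each prorated by the fraction of the peak inside
the region — deterministic and order-independent. The elbow cutoff
scales rank and signal each to [0, 1] and takes argmax(xᵢ − yᵢ), the
slope-1 tangent of the convex rank curve; ties break toward the larger
index (fewer SEs), regions strictly above the cutoff signal are super,
and a constant or perfectly linear curve (max gap ≤ 10⁻⁹) yields zero
SEs. The cutoff is invariant to affine rescaling of the signal vector.

Multi-set SE consensus reuses the merge-then-count semantics (the
study design this emulates keeps SEs in ≥ 4 of 6 resource sets, ≥ 2 of
3 treatment replicates). Tissue specificity counts catalog samples in
which a *single* catalog SE covers ≥ 70 % of the query SE's length —
coverage is measured on the query SE, and multiple catalog SEs do not
stack (a stacking variant exists as a config option, off by default,
because the external-catalog convention is ambiguous).

## eRNA candidates

The cascade merges enhancer regions within 50 bp, then drops regions
with ≥ 1 bp gene-body overlap, regions whose edge-to-edge distance to
the nearest TSS is < 3,000 bp (overlap ⇒ distance 0; "within 3 kb" is
read as strict), and regions within 3,000 bp of an H3K4me3 peak by the
same rule. Distances are measured from the region edge, not midpoint;
the choice is isolated in one function. The filters are conjunctive,
so the outcome is order-independent, and each candidate carries a
filter trace for audit. Expression retention uses plain
library-size CPM (each column scaled to 10⁶) with a strict threshold:
CPM > 1 in ≥ 2 samples. TMM-style normalization factors can be applied
upstream by the caller; the filter itself stays plain CPM.

## Loops and compartments

Two loops match when both anchor pairs overlap, in either pairing;
anchors are canonicalized on read so the test is symmetric, and
optional symmetric padding (default 0) is available. Consensus
clusters loops by single-linkage (transitive) matching and retains
clusters spanning ≥ 2 samples; the representative is the anchor-wise
union span with the supporting sample set attached. Differential
classification marks control-only clusters lost, treated-only gained,
and records both representatives for stable pairs. The top
loop-change genes are those whose promoter label sits on an anchor of
gained + lost loops with a count at or above the (1 − q) quantile
(default q = 0.05, numpy linear interpolation) of the positive-count
distribution — genes with zero changes are excluded from the
distribution, and threshold ties are all included.

Compartment windows classify by score sign (A > 0 > B; an exact zero
takes the neighbour majority, defaulting to B with a warning). Shifts
come either from an external significance flag column (emulating a
dedicated compartment-change caller, whose statistical model is out of
scope here) or from a |Δscore| ≥ 0.3 threshold with direction =
sign(Δ). The signal-change test is a one-sample two-sided *t*-test of
per-window mark deltas against zero with the n − 1 standard deviation
and n − 1 degrees of freedom; constant deltas raise rather than
returning a degenerate statistic. "One t-test" in the emulated design
is read as one-sample two-sided, matching the "differs from zero"
framing.

## Variant-to-gene

LD expansion keeps proxies with r² ≥ 0.8 (no published threshold
exists for the emulated analysis; the value is configurable and echoed
in outputs) within 1 Mb of their lead. The loop mechanism requires the
variant (a 1-bp interval) in one anchor and ≥ 1 bp of a gene promoter
in the other, testing both orderings and deduplicating
(variant, gene, loop) triples; a variant overlapping both anchors
yields assignments for genes on either side. The SE mechanism requires
the variant position and part of the promoter inside the same SE
interval. Closest genes use edge-to-edge distance to the gene body
with all ties reported. Peri-variant counts use the window
[pos − 5,000, pos + 5,001) — "within 5 kb" read as ± 5 kb — and count
gained/lost consensus peaks per mark with any overlap. Assignments are
computed independently against each loop set (control, treated) and
labeled.

## Gene sets, enrichment and the intersection matrix

The 16 gene sets are: DE genes; genes overlapping shifted compartment
windows; genes overlapping ATAC changes; SE changes; CRE changes;
activated/deactivated enhancers; per-mark changes for H3K27ac,
H3K27me3, H3K4me1, H3K4me3, H3K36me3 and CTCF; top-5 % loop-change
genes; and genes with changed promoter–enhancer, promoter–repressor
and promoter–SE loops. Gene–feature overlap means the feature touches
the gene body ∪ promoter (≥ 1 bp); membership is non-exclusive. CRE
changes are derived from the enhancer/promoter-mark peak dynamics
restricted to CREs. The "repressor" anchor class defaults to
H3K27me3/H3K9me3-marked segments and is overridable.

Over-representation is the one-sided hypergeometric tail
P(X ≥ k | N, K, n) per term (terms with no universe genes skipped),
with Benjamini–Hochberg FDR within each gene set's family. The
universe is all genes in the gene-model file, not only annotated
genes. The term × set matrix marks cells with FDR ≤ 0.05 and keeps
terms significant in ≥ 4 sets, ordered by descending row-sum.

## The synthetic study

The generator emulates the processed outputs of a
glucocorticoid-perturbation study in a cultured ocular cell system:
two conditions, three replicates, seven marks (the histone panel,
CTCF, ATAC), promoter-capture-style loops from three samples per
condition, 50 kb compartment score tracks, negative-binomial counts
with planted log₂ fold changes of ±2 for 20 % of genes, lead/proxy
variant tables, an SEdb-like catalog of 40 samples and five external
tissue loop catalogs.

The default scale — 2 chromosomes × 10 Mb, 304 genes, ~600 planted
peaks per mark, ~60 loop clusters — keeps generation plus the full
pipeline under a few seconds while exercising every code path; the
layout tiles each chromosome with 50 kb blocks (15 gene blocks, 2
enhancer blocks, 1 SE cluster, 1 decoy block, 1 utility block per
1 Mb period) so that planted features never collide and every planted
truth is exactly recoverable. Replicate peaks are jittered by
N(0, 25 bp) per edge and 10 % of peaks are dropped per replicate,
with drops rebalanced so each truth peak survives in at least *k*
replicates — the consensus logic is exercised (replicate-unique decoy
peaks must be excluded) without making exact recovery impossible by
construction. Randomness fans out from one seed through named child
generators, so outputs are byte-identical across runs.

What the generator does **not** emulate: read-level noise, peak-caller
artifacts, CHiCAGO score distributions, copy-number or mappability
structure, overlapping features competing for the same locus, and
partial/ambiguous truth (every planted signal is unambiguous).
Passing planted-truth tests therefore demonstrates the correctness of
the integration logic — overlap algebra, consensus, matching,
thresholds, statistics — not robustness to the messiness of real
chromatin data, where boundary effects and marginal signals will
produce imperfect precision/recall.

## Numerical choices and degenerate inputs

Pearson correlations of zero-variance rows are defined as 0 (with a
warning); the SE elbow returns zero SEs for constant or linear curves;
empty promoter windows, negative signals, overlapping compartment
records, mismatched window grids, zero library sizes, unknown leads
and missing gene ids all raise with the offending item named. The
statistics delegate to scipy/statsmodels (`ttest_1samp`,
`hypergeom.sf`, `multipletests(method="fdr_bh")`); tests pin them to
independently derived values (closed-form *t*, combinatorial
hypergeometric sums).

## Known limitations

* The pipeline consumes processed inputs only; peak calling, Hi-C
  processing, compartment-score estimation and differential-expression
  model fitting are upstream concerns.
* Loop consensus uses single-linkage clustering, which can chain
  nearby loops into one cluster on dense data; the per-sample
  representative union span grows accordingly.
* The quantile rule for top loop-change genes is sensitive to heavy
  ties in the count distribution (ties at the threshold are all
  included by design).
* Enhancer-state calls are binary per mark (peak overlap), ignoring
  signal strength.
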