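# Methods

This note records the conventions, parameter choices, and generator
design behind `selandscape`, in the spirit of a model-description
document: what is computed, under which assumptions, and what passing
tests do and do not demonstrate.

## Coordinates and interval algebra

All coordinates are 0-based half-open (`[start, end)`), the
BED/narrowPeak/bedGraph convention; the ROSE GFF dialect (1-based
inclusive) is converted only at the file boundary and inverted exactly
on read. Overlap requires at least one shared base; intervals that
merely touch (`a.end == b.start`) do not overlap. Merging at `max_gap`
joins intervals with `next.start − prev.end ≤ max_gap`, so touching
intervals merge at gap 0, matching `bedtools merge`. Exclusion-list
filtering removes a peak on ≥ 1 bp overlap (the bedtools default; no
fraction is applied). Chromosomes sort lexicographically with numeric
digit runs (`chr2 < chr10`), making all outputs platform-independent.

Point-to-interval distances (TSS to SE boundary, TSS to occupancy site)
are `start − pos` to the left, `pos − end` to the right, and 0 inside.
The 50-kb gene-association window and the 2,000-bp distal threshold are
both evaluated against this distance, with the association boundary
inclusive (exactly 50,000 bp still links) and the distal boundary
exclusive (distal means distance > 2,000 bp). A site 1–2,000 bp from a
TSS that does not contain one is *unclassified*: it enters no partition
statistic, and its count is logged rather than silently assigned.

## Coverage and signal

Coverage arrives as fixed-step bedGraph bins plus a stated library size
(total mapped reads, supplied as metadata because a real library
includes reads outside any covered region). Signal over a region is the
pro-rated sum of overlapping bins. BAM/CRAM parsing is out of scope by
design; whether duplicate reads were removed upstream is invisible to
this abstraction.

ROSE-style region signal is input-subtracted per-million coverage,
floored at zero:
`S = max(0, IP·10⁶/M_IP − input·10⁶/M_input)`. With no input track the
IP term is used alone and a warning is logged. The floor keeps ranks
well-defined on noisy low-signal regions; per-million scaling makes S
invariant to joint rescaling of reads and library size.

## ROSE-style calling

Peaks fully contained in ±2,500 bp of any TSS are retained as singleton
regions but neither nucleate nor join stitched regions, preventing
promoter H3K27ac from bridging enhancer clusters. Stitching is
transitive closure at gap ≤ 12,500 bp (inclusive). The super/typical
cutoff is the tangent-line criterion on the ascending ranked-signal
curve: with slope `m = (S_max − S_min)/n`, the cutoff index `x*`
minimizes the number of points on or below the slope-m line through
`(x, S_x)` — the discrete analogue of the point where the curve's
tangent reaches slope m. Ties break to the smallest index, so an
all-equal signal vector yields zero supers. The implementation is a
blocked O(n²) comparison using the form `s_i − s_x ≤ m·(i − x)`; the
test suite checks it against an independent per-index enumeration of the
same inequality, which makes the comparison exact rather than
tolerance-based. Supers are `S > cutoff`, strictly.

## CREAM-style calling

The published CREAM procedure selects gap thresholds through
order-statistics over window sizes; this package implements a
documented surrogate driven by the same two reported parameters
(`MinLength = 1000`, `peakNumMin = 2`) plus a quantile: neighbor gaps on
real peak landscapes are bimodal on the log scale (an intra-cluster mode
far below the genome-wide background mode), the two modes are separated
by an exact 1-D Otsu/2-means scan on log gaps, and the clustering
threshold is the `gap_quantile` (default 0.95) quantile of the lower
mode. Typical background gaps therefore sit far above the threshold,
and clusters are runs of consecutive peaks with gaps at or below it,
reported when they contain ≥ `peakNumMin` peaks and span ≥ `MinLength`
bp (first peak start to last peak end). This is a CREAM-*style* caller,
not a line-for-line port; the chosen threshold is recorded in the call's
parameters. A global quantile of the full gap distribution was rejected
because whenever isolated peaks outnumber clustered ones the upper
quantile of all gaps exceeds the background spacing and the whole
chromosome collapses into one cluster.

Degenerate inputs: fewer than two peaks on every chromosome gives an
empty call; an all-equal gap distribution uses that gap as threshold and
lets the size/length filters decide.

## Per-sample merge, consensus, annotation

Super regions from all callers and replicates of a sample are
concatenated and merged at gap 0. Cross-sample sharing uses asymmetric
fractional overlap (`-f` semantics, default 0.2, inclusive): region A is
shared with sample Y if a single Y region covers ≥ 20% of A's length;
pairwise flags are assembled into intersection patterns one sample at a
time (Intervene's pairwise behaviour). As the fraction approaches 0 the
rule degenerates to ≥ 1 bp overlap; at 1.0 it requires A to be fully
covered. Gene association is TSS-within-window (default 50 kb),
strand-agnostic, many-to-many with a deduplicated gene list; overlap-
only and nearest-gene modes exist behind flags but are not defaults.
Oncogene flagging is case-normalized exact symbol matching.

## Occupancy analysis

BAF sites are SMARCC1 peaks overlapping (≥ 1 bp) any DPF2 peak; PBAF
likewise with ARID2; built separately per condition, then unioned and
merged (gap 0) into the full site set with complex-class and
condition-origin provenance. The site interval is the SMARCC1 peak (and
the site center its summit) because summits define peak centers and
summits belong to whole peaks; a literal-intersection-segment mode is
available behind a flag. Enrichment is
`(IP·10⁶/M + 0.1)/(input·10⁶/M + 0.1)` — strictly positive, equal to 1
on all-zero data, invariant under joint read/library rescaling; the
pseudocount 0.1 stabilizes low-coverage ratios. Assays without an input
(e.g. ATAC) use per-million IP plus pseudocount. Log₂ fold-changes are
`log₂(E_reexpression/E_control)`, always finite.

Fold thresholds are applied on the linear scale: "1.5-fold" means
|log₂FC| ≥ log₂ 1.5 ≈ 0.585 (inclusive), "2-fold" means |log₂FC| ≥ 1.
Concordance quadrants classify each site as both-down, both-up,
discordant, or gray (any axis inside the threshold band); the four
fractions sum to 1 per partition group and are order-invariant.
Histogram frequencies are weighted by group size (bar height =
count/group size, so each group sums to 1), making groups of different
sizes comparable. The
strong-decrease statistic is the fraction of sites per partition with
H3K27ac log₂FC ≤ −1; the headline ratio divides the in-SE fraction by
each other partition's fraction, reported infinite and flagged when a
denominator is empty.

## DE filtering and contingency

Significance is |log₂FC| ≥ 1.5 (inclusive — the printed "±1.5" is read
as the admitted boundary) AND adjusted p < 0.05 (strict, as printed);
missing adjusted p is non-significant. The 2×2 table (direction ×
SE-proximity) counts genes, not SE-gene links, over significant genes
only, and is tested by Pearson chi-square without continuity correction
— matching spreadsheet chi-square functions — with df 1. A zero margin
flags the result degenerate instead of raising. Down/up ratios are
reported per stratum.

## Synthetic-data generator

The generator's defaults are the demo study conditions under which all
recovery properties are stated.

*Landscape* (per sample): two 2-Mb chromosomes; 200 isolated enhancer
peaks of 600 bp placed with > 12.5 kb spacing so each is its own
stitched region (two chromosomes because that spacing for 200 peaks
cannot fit on one 2-Mb chromosome); 10 planted SEs of 6 peaks with
0.5–1.5 kb intra-cluster gaps at 5× the isolated amplitude; Poisson
background (0.5 reads per 50-bp bin) plus triangular summit-centered
bumps; an exclusion list with decoy peaks inside it; 120 genes with one
guaranteed within 10–30 kb of each SE and TSSs kept ≥ 6 kb from SE
spans so the TSS-exclusion rule cannot eat planted constituents. A
three-sample sharing design (4 common / 3 shared-in-2 / 3 unique)
drives the consensus tests. Coverage is binned, not read-level: the
pipeline consumes bins, so read simulation would add cost without
exercising more code.

*Occupancy*: 500 SMARCC1 peaks per stratum (TSS-proximal /
distal-in-SE / distal-out) on a dedicated chromosome of 8-kb units,
guaranteeing every distal site is > 2 kb from any TSS by construction.
DPF2/ARID2 co-peaks are Bernoulli draws (rates 0.85 / 0.5); peaks with
no partner are not sites. Quadrant labels are assigned in *exact*
planted proportions (in-SE both-down 0.6, outside 0.2; strong-decrease
0.3 vs 0.1 nested within both-down) and per-site log₂ fold-changes are
drawn from ranges that keep a ≥ 0.03 margin from the ±log₂ 1.5 and ±1
boundaries. Tracks are noise-free and constructed so the measured
fold-change equals the planted draw exactly (inputs identical across
conditions cancel; the pseudocount distortion is bounded below the
margin). Recovery tests therefore exercise the full measurement chain
— file round-trip, site construction, enrichment, partition, quadrant
counting — rather than sampling noise.

*DE*: 400 significant genes (|log₂FC| ≥ 1.5, adjusted p < 0.05) plus
200 filler genes failing one cutoff or the other. Directions are true
Bernoulli draws: non-SE genes have down/up odds 0.52 and SE-linked
genes have those odds times a planted odds ratio (default 3) — chosen
because these odds reproduce the scale of stratum ratios seen in
SWI/SNF-deficient SE studies (≈1.5 down/up near SEs vs ≈0.5 away).
Bernoulli (rather than exact-count) assignment is what makes the
chi-square type-I calibration test meaningful.

Determinism: every output file draws from its own labeled substream of
the master seed (`PCG64` seeded with `[seed, crc32(label)]`), so
identical config + seed give byte-identical trees and adding an output
never perturbs another.

## Problem sizes and numerical choices

The demo problem sizes (4 Mb of genome, ~230 peaks/sample, 1,500
occupancy units, 600-gene DE tables, 100-replicate calibration loops)
were chosen so the entire suite and the acceptance script run in
minutes on a single CPU while leaving the recovery margins wide.
Floating-point ties in the tangent cutoff are resolved by evaluating the
comparison in the single algebraic form `s_i − s_x ≤ m·(i − x)`; rank
ties use stable sorting; all tie-breaks go to the smallest index.

## Limitations

* The synthetic landscape has no replicate-level biological noise, no
  GC/mappability structure, no copy-number variation, and bin-level
  rather than read-level sampling; passing recovery tests shows the
  algorithms and plumbing are correct, not that real-data SE counts
  would be reproduced.
* Printed site counts and percentages from any particular sequencing
  study depend on the deposited raw data and upstream alignment/peak
  calling, which are out of scope; this package reproduces the
  *procedures*, and its acceptance metrics are planted-truth recoveries
  of the same statistical structure.
* The CREAM-style caller is a surrogate (see above), faithful to the
  reported parameters but not to the full published threshold-selection
  procedure.
* Differential-binding models (csaw/DESeq2) and expression
  quantification are upstream; their output tables are consumed, never
  fitted here.
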