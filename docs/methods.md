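# Methods

This note documents the models, conventions and numerical choices behind
`clonatlas`, and what the synthetic-cohort tests do and do not establish
about real data.

## Coordinates and interval semantics

All intervals are 0-based half-open (BED convention). Two intervals overlap
iff they share at least one base; bookended intervals ([0,10) and [10,20))
do not overlap and are never merged. Fragment-in-peak membership, peak
merging and atlas counting all use this single definition, and each is
validated in the test suite against per-base / exhaustive-loop oracles.

## Sample QC

A sample passes iff `total_fragments >= min_fragments` (default 2,000,000)
AND `FRiP >= min_frip` (default 0.2), both inclusive. FRiP is the fraction
of a sample's fragments overlapping ≥ 1 bp of any of that sample's own peak
calls — the gate is applied per library before any atlas exists, so a
sample's QC verdict cannot depend on other samples. Each fragment counts
once however many peaks it touches. A library with zero fragments has
undefined FRiP and is reported as failing with an explicit reason rather
than dividing by zero. We count fragments where sequencing pipelines often
count reads; the thresholds are configurable for that reason.

## Peak atlas and normalization

The atlas is the connected-overlap closure (single-linkage transitive union)
of all passing samples' peaks: overlapping chains collapse into one atlas
peak. Raw counts are fragments overlapping each atlas peak (a fragment
spanning the gap between two atlas peaks increments both rows — documented,
and rare at typical fragment lengths). Normalization is

    normalized[i, j] = (raw[i, j] / total_j) / mean_j'(raw[i, j'] / total_j')

where `total_j` is the sample's total mapped fragments (not just in-atlas).
Every retained row therefore has mean exactly 1; rows whose all-sample mean
rate is 0 are dropped and logged rather than pseudocounted, to avoid
fabricating accessibility. No quantile or additional depth re-scaling is
applied. Whether counting should use full-overlap or midpoint semantics is
genuinely open; overlap semantics is the default and the implementation
point where the alternative would go is `count_matrix`.

## Clustering and embeddings

Samples are clustered by Ward linkage on Euclidean distances over peak
dimensions (the squared-Euclidean "Ward.D2" objective, i.e. the textbook
Ward criterion — chosen deliberately where some environments historically
offered an ambiguous "ward"). Peaks are clustered by k-means (Lloyd,
k-means++ initialization, best of 10 restarts by within-cluster sum of
squares, fixed seed) with default k = 15, on the normalized matrix exactly
as built — no z-scoring, since the normalization already puts every peak on
a mean-1 scale. Cluster labels are relabeled 1..k by descending size so
label identity is reproducible. Embedding defaults: t-SNE perplexity 5
(requiring > 3·perplexity + 1 samples), UMAP n_neighbors 7, n_components 2;
PCA is deterministic, the stochastic methods are seeded.

## Peak-to-gene assignment and genomic context

A peak's target gene is the gene with the nearest TSS, measured from the
peak midpoint, if that distance is strictly less than 10 kb. The midpoint
anchor is a design choice: merged atlas peaks carry no summit, and the
midpoint is the only anchor that is well defined after merging
(nearest-edge is available as configuration). Equidistant ties break toward
the lexicographically smaller gene id, for determinism. Context labels are
decided at the midpoint with precedence promoter > exon > intron >
intergenic; the promoter is a strand-aware 1 kb window upstream of the TSS
plus the TSS base (the window size is a convention, not an inference, and is
configurable). Genes without exon structure count as single-exon.

## Differential expression

Counts are modeled per gene as NB(μ, α) with Var = μ + αμ², log link,
design intercept + group, and log median-of-ratios size factors as offsets.
The Wald statistic is coefficient/SE against the standard normal, two-sided,
BH-adjusted over tested genes (all-zero genes are excluded from testing and
from the BH denominator); significance is padj < 0.05. No log-fold-change
threshold is imposed beyond the significance gate.

Dispersion estimation needed care at minimal replication (2 vs 2). The plain
per-gene profile likelihood is biased low because the two group means absorb
half the residual degrees of freedom, and even the Cox–Reid adjusted profile
likelihood (which we use, maximized over log α with an MoM start and a floor
of 1e-8) leaves single-gene estimates noisy enough to make the normal-
reference Wald test anti-conservative. We therefore fit a parametric
mean–dispersion trend a(μ) = a0 + a1/μ across genes by iteratively trimmed
least squares (genes > 10-fold off the fit are excluded and the fit
repeated; fewer than 10 usable genes degenerates to the median) and floor
each gene's dispersion at the trend. This is the conservative "maximum"
sharing mode: information is shared across genes only upward, never
shrinking a gene below its own estimate. Calibration is established by
simulation: on a 2,000-gene complete null (2 vs 2, α = 0.05) the realized
rate of padj < 0.05 calls is at the binomial-noise level of zero, while
planted |log2FC| = 2 genes at mean 500 are detected with power ≳ 0.95 and
median |LFC error| ≈ 0.2. No independent filtering or outlier refitting is
applied. `pydeseq2` is used in one test as an independent cross-check of
the fold-change estimates (correlation > 0.95 on a shared matrix), never as
the implementation.

## Integration ("actively regulated" genes)

For a direction (up/down), the universe is the significant preferential set
for the contrast, optionally intersected with a user-supplied category list
(GMT). A gene is "targeted" by a cluster set iff it is the assigned
nearest-TSS target of at least one peak in those clusters — no distance
re-check beyond the assignment. The report is |targeted ∩ universe| /
|universe|, undefined (and reported as such) for an empty universe. The
fraction is monotone non-decreasing in the cluster set by construction.

## Motif analysis

A PWM stores per-position base probabilities and a background composition
(default uniform). Scores are log2(p/background) summed over positions; N
contributes 0 bits. Both strands are scanned (reverse-complement matrix on
the forward sequence). The default hit threshold is 80 % of the motif's
maximum achievable score — common practice absent a stated cutoff, and
per-motif configurable. Cluster enrichment is a one-sided hypergeometric
test of hit-bearing peaks in the target cluster against target + background,
where the default background is all other atlas peaks — a self-contained
choice in place of an external tool's genome-wide background; a GC-matched
background is the natural extension point. −log10(p) > 100 is a display
gate for dot plots, not a statistical threshold; both raw and gated tables
are emitted. Density profiles histogram hit starts by offset from peak
center into 20 bp bins over a 2 kb window, normalized per bin by the number
of peaks whose window covers that bin (so chromosome-edge truncation does
not bias the shape); without truncation the profile sums to hits per peak.

## Term enrichment

One-sided hypergeometric upper tail per term, fold enrichment
(k/n)/(K/N), BH FDR across tested terms. Term memberships are intersected
with the universe first; terms annotating fewer than 3 universe genes are
skipped as noise (configurable). The default universe is the set of genes
tested for DE. FDR < 0.01 is the dot-plot display convention. No GO-graph
ancestor propagation is performed — annotations are taken as given in the
GMT.

## Cross-dataset comparison

Shared-motif counting is plain set intersection of named motif sets, so it
requires a shared motif namespace between the two collections. Expression
bias of a gene set across a foreign region × gene atlas divides each region
by its mean over ALL genes (making every region's all-gene mean 1, which
cancels region-wise intensity differences of in-situ data), then reports
per-region means over the set and a descriptive bias score max/median; no
test statistic is attached because the intended use is a qualitative
negative control. Ortholog translation uses a user-supplied two-column
table; foreign genes hit by more than one own gene are dropped entirely so
the mapping used is 1:1.

## Synthetic cohort generator

The generator emulates the data structure of a ~100-sample clonal-unit
study: ~10 region labels (pallium-like and subpallium-like), truth peaks of
width 500 bp partitioned into OCR clusters, a cluster→region activity map
in which one distinct region owns private clusters (closed in every other
region) while the other regions' specific clusters are closed in it, and a
cluster common to all regions. A sample's peak calls are its region's active
truth peaks, each re-centered by N(0, 20 bp) and dropped with probability
0.05, so atlas merging is non-trivial. Fragments are fixed-length 200 bp
(echoing the fragment-extension size used when calling peaks on real data):
with probability `frip_target` (default 0.4) a fragment falls uniformly
inside one of the sample's own peaks, otherwise uniformly on the genome —
the simplest null with a known FRiP expectation, concentrating realized
FRiP within ±0.05 of target at ≥ 50k fragments. Planted QC failures
alternate between half-threshold depth and quarter-threshold FRiP. Depths
default to 60–120k fragments with a 50k QC threshold — a deliberate
desk-scale rendition of the real-data 2-million-fragment gate; the qc module
itself defaults to the real thresholds. Expression counts are NB with
gene-wise log-normal baselines, planted genes shifted by 2^±lfc in the
first condition at a stated baseline mean; an explicit planted-gene list
allows coupling DE genes to OCR-cluster targets at a stated rate c, which
is what makes the integration stage testable quantitatively. Motif planting
writes the PWM consensus at a Gaussian offset around peak centers. All
generators are deterministic given their seed, and every planted structure
is recorded in a `TruthRecord` that round-trips through JSON.

What the generator does NOT model — and hence what passing tests do not
show about real data: read-level artifacts (duplicates, mappability,
alignment error), GC or accessibility-dependent coverage bias, correlated
biological replicates, dispersion heterogeneity across genes (a single α is
planted), overlapping gene models, and real motif redundancy within TF
families. Results on real cohorts depend on upstream alignment and peak
calling, which are outside this package.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problem sizes chosen as the
package's own defaults: genomes of 1–6 Mb, 40–100 samples, 300–1200 atlas
peaks, 2,000–3,000 genes, 20-replicate motif recovery. The pipeline fans a
single global seed out per stage (seed + stage index); stage outputs are
pure functions of (inputs, config, seed), verified by SHA-256 digest
comparison across reruns.
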