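# Methods

This note documents the models, rules and numerical choices behind
`bivatlas`, and what the synthetic study does and does not establish.

## Coordinates and interval algebra

All region logic runs on 0-based half-open intervals (BED convention);
1-based inputs (Illumina manifest `MAPINFO`) are converted at the reader
boundary, and chromosome dialects (`1` vs `chr1`) are normalized to the
`chr` form. Normalization sorts and merges overlapping *and* gap-0 adjacent
intervals; strand is ignored by the algebra (peaks are unstranded).
Intersection, subtraction and overlap queries are implemented directly on
sorted integer arrays and are required (by test) to be bit-identical to a
base-wise boolean-array oracle; the width filter inside intersection keeps
pieces of width ≥ `min_width`.

## High-confidence region calling

* Per line, a **bivalent domain** is each maximal H3K4me3 ∩ H3K27me3 piece
  of width ≥ 1000 bp. The domain's coordinates are the overlap itself (not
  the union of the two parent peaks): the overlap is the only stretch both
  marks demonstrably cover. "At least 1 kbp" is read inclusively: a
  1000-bp overlap passes.
* **Cross-line consensus (bivalent)**: per-line domains are union-merged
  into maximal connected regions; a line supports a region if ≥ 1 bp of its
  domains overlaps it. HC = support by all lines (`n_required` defaults to
  the number of lines). A stricter all-lines per-base intersection mode is
  available via `consensus_mode="intersection"`.
* **Single-mark HC lists**: per-base intersection across all lines of the
  one mark's peaks, runs ≥ 1000 bp, then any candidate overlapping (≥ 1 bp)
  a bivalent domain of *any* line is discarded whole (no trimming). The
  intersection is implemented as a per-base support count ≥ `n_required`,
  which generalizes the all-lines AND.
* Sex chromosomes (`chrX`, `chrY`) are excluded from every output list
  because the contributing cell lines are of mixed embryo sex.

The three HC lists are pairwise disjoint by construction on data where
single-mark consensus runs do not straddle sub-1-kb double-marked stretches
(the generator never plants such regions; the property is asserted on the
synthetic study, not claimed universally).

## Annotation

Flags are set by ≥ 1 bp overlap (the minimum-overlap is configurable).
The mutually exclusive feature class uses the precedence **CGI/promoter >
promoter > gene body > intergenic**, which makes the per-class counts a
partition. Promoters are TSS ± 1000 bp, clipped at position 0. A region
overlapping promoters of several genes is attached to all of them; the
per-gene signature is `none` (no marked promoter), the common category, or
`mixed` — mixed genes are excluded from expression summaries and exported
gene lists. Retroelement profiles tile ± 4000 bp around each TSS in 100-bp
bins (resolution configurable), oriented by strand so negative offsets are
upstream; each bin's value is the fraction of TSS whose bin interval
touches a repeat of the class (default classes LINE, SINE, LTR —
retrotransposons; DNA transposons are excluded by default but the class
list is configurable).

## Signal tracks and factor clustering

Tracks are piecewise-constant bedGraph coverage; window statistics are
computed exactly from a cumulative integral (no re-binning error) and
scaled to RPM (raw × 10⁶ / total reads; the total defaults to the track's
own integral). Features for clustering are the **summed** RPM over the
region ± 1 kbp per factor (EZH2, PolII, TAF1, TCF12); a mean-based variant
is available. Before K-means the features are log2(x+1)-transformed and
z-scored per factor — untransformed RPM would let the strongest factor
dominate the Euclidean metric; the transform is configurable.

K-means uses Lloyd iterations (tolerance 1e−6), 50 random starts, fixed
seed 1729. Rows are put into a canonical lexicographic order before
fitting and labeled by nearest centroid afterwards, so the partition is
invariant to input order under a fixed seed. Semantic labels: cluster 1 =
highest mean PolII+TAF1, cluster 2 = highest mean EZH2 among the rest,
cluster 3 = the remainder; ties break by cluster size (descending), then
raw label.

Histone marks are assigned to a region only when an overlapping peak exists
in both reference lines (H1 and H9); transcription-factor occupancy keeps
peaks with FDR < 0.05 (narrowPeak −log10 q converted to FDR). Category
contrasts use Pearson's chi-squared on the 2×2 table, 1 df, no continuity
correction; a zero expected cell is an error, not a silent zero.

## Expression integration

Summaries are on log2(RPKM + ε) with ε = 0.1 — the pseudocount bounds the
log scale for silent genes at about −3.3 while leaving expressed genes
essentially untouched; it is configurable. Cross-tissue comparisons
normalize each tissue to the median of H3K4me3-only-signature genes (their
expression is globally stable across tissues), so 0 means "as expressed as
a typical constitutively active gene". Quantiles (IQR, quartile summaries)
use linear interpolation (type 7), stated because IQR values depend on the
rule. Mixed-signature genes are excluded throughout.

## Differential methylation

The test is an **unpaired** two-group comparison (tumor group vs matched
normal group) on β values directly — every threshold of interest (Δβ >
0.25, β bands at 0.1/0.3/0.7) lives on the β scale; a paired design is
exposed as an option but not the default since the original design matrix
is not fixed by the upstream literature. Per probe, the pooled residual
variance s²_g (d_g = n₁+n₂−2 df) is shrunk by empirical Bayes:

    s²_g,mod = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

with (d₀, s₀²) estimated by method of moments on z_g = log s²_g: with
e_g = z_g − ψ(d_g/2) + log(d_g/2), d₀ solves ψ′(d₀/2) = 2·[Var(e) −
mean ψ′(d_g/2)] via Newton inversion of the trigamma function (tolerance
1e−8, ≤ 100 iterations), and s₀² = exp(mean e + ψ(d₀/2) − log(d₀/2)).
When the observed spread of log variances does not exceed its sampling
expectation, d₀ = ∞ and s₀² is the arithmetic mean of the sample variances
— in that regime (e.g. all probe variances equal) the moderated t equals
the ordinary t exactly, as does the d₀ = 0 limit. The moderated t is
referred to a t distribution with d₀ + d_g df (normal when d₀ = ∞). If the
prior fit fails the code falls back to the ordinary t with a warning.

Probes with missing β are tested only with ≥ 2 non-missing values per
group; untested probes are flagged, not silently dropped. Multiplicity uses
Benjamini–Hochberg step-up q-values. Calls: hyper iff Δβ > 0.25 and
q < 0.05; hypo iff Δβ < −0.25 and q < 0.05 (the effect threshold is applied
symmetrically — the negative sign on the hypo side is the only coherent
reading and is configurable). CIMP-positive and CIMP-negative tumors are
analyzed separately, each against the normals matched to that arm's tumors;
tumors with CIMP `NA` are excluded, and an arm with fewer than two tumors
(or normals) is reported as absent rather than analyzed. Category
distributions over {none, bivalent, K4only, K27only} are fractions of the
called probes (reported as absent when there are no calls, never as a row
of zeros), with the all-probe distribution as reference. Recurrence keeps
probes hyper in ≥ 5 of 8 per-type analyses, per arm, and reports the
promoter regions containing them; it is monotone non-increasing in the
threshold by construction.

## Synthetic study: what it emulates

The generator is the study-condition definition, not a tuning knob. Default
scale: 5 autosomes × 10 Mb + chrX 5 Mb; 200 bivalent (+10 on chrX), 200
H3K4me3-only, 200 H3K27me3-only and 100 unmarked-CGI regions, spaced ≥ 27 kb
apart, widths 1.2–3 kb; 1200 genes; 20,000 probes; 20 tumor/normal pairs ×
8 tumor types; 34 tissues. Everything runs in well under a minute on one
CPU. Planted structure:

* promoter/CGI concentration per category chosen to reproduce the observed
  75/74/24.5% promoter and 71/61/1.5% CGI-promoter proportions;
* repeats thinned to 30% density within ± 1 kb of bivalent TSS (70%
  elsewhere near TSS), reproducing the depletion gradient at bivalent
  promoters;
* peak sets: the H3K4me3 peak equals the region, the H3K27me3 peak extends
  1 kb both ways, so the per-line overlap is the region itself and the
  zero-jitter/zero-dropout study recovers the planted lists exactly;
  per-line dropout at rate q makes the expected all-lines support fraction
  (1−q)⁵;
* factor tracks: per-region bump amplitudes by cluster (cluster 1
  PolII/TAF1 ≈ 120, cluster 2 EZH2 ≈ 120 / TCF12 ≈ 70, cluster 3 ≈ 40
  reads) with log2 within-cluster SD 0.4 — about a 4-SD separation per
  informative factor — plus a weak Poisson background (0.001 reads/bp);
  cluster proportions 17/22/61%;
* methylomes: CGI-promoter probes unmethylated (β ≈ 0.07), gene-body
  unmarked-CGI probes methylated (β ≈ 0.8), H3K27me3-only probes
  methylated (β ≈ 0.78); per-sample noise is truncated normal, SD 0.05
  (chosen over a beta distribution for simplicity; configurable).
  Hypermethylation (Δβ = 0.4) is planted in tumor samples per (type, CIMP
  arm) with 70% of each planted set drawn from cluster-2 bivalent CGI
  probes, and a pan-cancer subset recurring in ≥ 5 types per arm; a small
  hypomethylated set is planted at methylated gene-body probes. A couple of
  tumors carry CIMP `NA` to exercise exclusion;
* expression: log-normal RPKM; H3K4me3-only genes high everywhere
  (log2 ≈ 5), H3K27me3-only silent (≈ −6), bivalent genes switch on/off per
  tissue with cluster-dependent on-rates (0.80/0.12/0.50) and levels, which
  yields the class ordering in every tissue and larger cross-tissue IQR for
  bivalent genes.

**What passing tests do not show about real data**: the generator plants
clean rectangular peaks, independent Gaussian β noise, and
regularly spaced regions; real ChIP-seq has irregular peak shapes,
copy-number and cell-composition artifacts, correlated probes, and
batch structure. Recovery results here validate the *logic* of the
pipeline (set algebra, consensus rules, shrinkage, thresholds), not its
statistical power on genome-scale data, and the original study's headline
counts (thousands of regions genome-wide) are outside desk scale by design.

## Determinism and degenerate inputs

All generators and the pipeline are deterministic under a fixed seed;
`run-all` outputs are byte-identical across reruns (run logs carry
parameters, seeds and input checksums, and no timestamps). Degenerate
inputs have defined behavior: empty region lists produce header-only
exports; an expression class or call direction with no members is reported
absent rather than zero; a tissue with no H3K4me3-only genes is an error
for normalization; overlapping regions are an error for probe mapping
(the category partition would be ambiguous).
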