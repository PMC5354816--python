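# bivatlas

Calling, annotating and integrating **high-confidence bivalent chromatin
regions** with DNA-methylation-array and expression data.

## The problem

In embryonic stem cells, many CpG-island (CGI) promoters carry *bivalent*
chromatin — both the active H3K4me3 and the repressive H3K27me3 marks —
holding developmental genes in a poised state. These bivalent CGIs are the
preferred targets of aberrant DNA hypermethylation in tumors. Quantifying
that instructive program requires (i) a genome-wide, multi-cell-line list of
bivalent / H3K4me3-only / H3K27me3-only regions with exact coordinates, and
(ii) a way to project that chromatin signature onto Infinium methylation
arrays (HM450K/EPIC) so that tumor-vs-normal differential methylation can be
stratified by stem-cell chromatin state.

`bivatlas` implements that pipeline for epigenomics researchers, end to end:

1. **Domain calling** — per cell line, a bivalent domain is every maximal
   interval where an H3K4me3 peak and an H3K27me3 peak overlap by ≥ 1 kbp.
   Per-line domains are union-merged across lines; regions supported by all
   lines are *high-confidence (HC)*. H3K4me3-only and H3K27me3-only HC lists
   are the all-lines consensus of a single mark (≥ 1 kbp) minus anything
   bivalent in any line. Sex chromosomes are excluded. The interval algebra
   is exact (0-based half-open) and tested bit-identically against a
   base-wise boolean oracle.
2. **Annotation** — CGI / promoter (TSS ± 1 kbp) / gene body / intergenic
   classification with a fixed precedence, enhancer overlap, per-gene
   promoter signatures (genes whose marked promoters disagree are `mixed`
   and excluded downstream), and strand-oriented retroelement frequency
   profiles (± 4 kbp around TSS).
3. **Factor clustering** — each HC bivalent region (± 1 kbp) is summarized
   by the summed RPM of EZH2, PolII, TAF1 and TCF12; K-means (k = 3 on
   log2, z-scored features) plus semantic relabeling gives cluster 1 =
   PolII/TAF1-high, cluster 2 = EZH2-high (PRC2-defined), cluster 3 =
   intermediate.
4. **Expression integration** — log2 RPKM normalized per tissue to the
   median of H3K4me3-only genes; per-class and per-cluster medians and
   cross-tissue interquartile ranges.
5. **Methylation integration** — array probes are mapped to HC regions;
   tumor vs matched-normal differential methylation per tumor type and CIMP
   arm uses an empirical-Bayes **moderated t**: per-probe variances are
   shrunk via s²_g,mod = (d₀s₀² + d_g s²_g)/(d₀ + d_g) with the prior
   (d₀, s₀²) fit by method of moments on log sample variances, and t referred
   to d₀ + d_g degrees of freedom. Probes are called hyper/hypo at
   BH-FDR < 0.05 and |Δβ| > 0.25; pan-cancer recurrence keeps probes hyper
   in ≥ 5 of 8 tumor types.
6. **Synthetic data** — a first-class seeded generator plants all of the
   above structures (5-line peak sets with jitter/dropout, 3-cluster factor
   tracks at 17/22/61% proportions, β matrices with hypermethylation planted
   preferentially at cluster-2 bivalent CGIs, tissue-switching expression)
   with machine-readable truth, so every stage is testable without
   downloads.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
genome (5 autosomes × 10 Mb + chrX):

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_call_hc_regions.py
python analysis/03_annotate_regions.py
python analysis/04_cluster_bivalent_promoters.py
python analysis/05_expression_by_signature.py
python analysis/06_tumor_methylation.py
```

Driver 02 prints, for seed 1:

```
merged bivalent domains: 200 (200 supported by all five lines -> high-confidence)
HC bivalent: n= 200  median width=2171 bp
HC K4only  : n= 200  median width=2104 bp
HC K27only : n= 200  median width=2105 bp
```

— with zero boundary jitter and no dropout the HC lists recover the planted
regions exactly. Driver 03 shows the planted feature structure (bivalent and
H3K4me3-only regions CGI/promoter-rich, H3K27me3-only regions CGI-poor):

```
K27only :   0.5% CGI/promoter,  24.0% in a promoter
K4only  :  60.0% CGI/promoter,  75.5% in a promoter
bivalent:  73.5% CGI/promoter,  78.5% in a promoter
```

Driver 04 recovers the three factor-occupancy clusters (sizes 23.0% /
16.5% / 60.5% for seed 1; the planted proportions are 17/22/61%) with
cluster 1 PolII/TAF1-high and cluster 2 EZH2-high. Driver 05 shows the
expression hierarchy per tissue (median log2(RPKM+0.1): H3K4me3-only 5.02 >
bivalent 1.11 > H3K27me3-only −3.11) and that cluster-1 bivalent genes are
the most expressed (normalized median −0.80) while cluster-2 genes are the
most repressed (−7.09). Driver 06 reports, for every tumor type and both
CIMP arms, that hypermethylated probes concentrate in bivalent regions
(73–84% of hyper calls) and within them in cluster 2 (62–81%), and counts
pan-cancer recurrent probes (hyper in ≥ 5 of 8 types).

The same pipeline is available as a CLI (`bivatlas simulate|call-domains|
annotate|cluster|expression|methylation|export|run-all`); `run-all` is
byte-for-byte reproducible under a fixed config and seed.

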