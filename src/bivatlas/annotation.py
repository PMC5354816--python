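"""Genomic-feature annotation of consensus regions.

Regions are flagged by >= 1 bp overlap with CpG islands, promoters
(TSS +/- 1 kbp), gene bodies and enhancers, and assigned one mutually
exclusive feature class by the precedence

    CGI/promoter > promoter > gene body > intergenic.

Per-gene promoter chromatin signatures collapse multi-promoter genes:
a gene is classed by the common category of all its marked promoters,
or 'mixed' when marked promoters disagree (mixed genes are excluded from
expression and ontology input lists downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .domains import ConsensusRegion
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "AnnotationBundle",
    "AnnotatedRegion",
    "build_promoters",
    "annotate_region",
    "annotate_regions",
    "promoter_signatures",
    "retroelement_profile",
    "FEATURE_CLASSES",
]

FEATURE_CLASSES = ("CGI/promoter", "promoter", "gene body", "intergenic")

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "other")


@dataclass
class AnnotationBundle:
    """Genome annotation inputs.

    ``genes``: DataFrame with one row per TSS — columns
    gene_id, chrom, tss (0-based), strand, start, end (gene body).
    ``repeats``: dict repeat class -> IntervalSet.
    """

    genes: pd.DataFrame
    cgis: IntervalSet
    repeats: Dict[str, IntervalSet]
    enhancers: IntervalSet
    promoter_flank: int = 1000

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss", "strand", "start", "end"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"genes table missing columns: {sorted(missing)}")
        self.promoters = build_promoters(self.genes, self.promoter_flank)
        self.gene_bodies = IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in self.genes.itertuples()
        ).normalize()


@dataclass
class AnnotatedRegion:
    region: ConsensusRegion
    is_cgi: bool
    is_promoter: bool
    is_cgi_promoter: bool
    feature_class: str
    enhancer_overlap: bool
    gene_ids: List[str]


def build_promoters(genes: pd.DataFrame, flank: int = 1000) -> IntervalSet:
    """One promoter interval [TSS-flank, TSS+flank) per TSS, clipped at 0."""
    ivs = []
    for r in genes.itertuples():
        start = max(0, int(r.tss) - flank)
        ivs.append(GenomicInterval(r.chrom, start, int(r.tss) + flank))
    return IntervalSet(ivs).normalize()


def _promoter_interval(chrom: str, tss: int, flank: int) -> GenomicInterval:
    return GenomicInterval(chrom, max(0, tss - flank), tss + flank)


def annotate_region(
    region: ConsensusRegion, bundle: AnnotationBundle, min_bp: int = 1
) -> AnnotatedRegion:
    """Flag one region against the bundle; >= 1 bp overlap sets each flag."""
    iv = region.interval
    is_cgi = bundle.cgis.overlaps_any(iv, min_bp)
    is_promoter = bundle.promoters.overlaps_any(iv, min_bp)
    is_cgi_promoter = is_cgi and is_promoter
    if is_cgi_promoter:
        feature_class = "CGI/promoter"
    elif is_promoter:
        feature_class = "promoter"
    elif bundle.gene_bodies.overlaps_any(iv, min_bp):
        feature_class = "gene body"
    else:
        feature_class = "intergenic"
    enhancer_overlap = bundle.enhancers.overlaps_any(iv, min_bp)
    gene_ids = sorted(
        {
            r.gene_id
            for r in bundle.genes.itertuples()
            if r.chrom == iv.chrom
            and max(iv.start, max(0, int(r.tss) - bundle.promoter_flank))
            < min(iv.end, int(r.tss) + bundle.promoter_flank)
        }
    )
    return AnnotatedRegion(
        region=region,
        is_cgi=is_cgi,
        is_promoter=is_promoter,
        is_cgi_promoter=is_cgi_promoter,
        feature_class=feature_class,
        enhancer_overlap=enhancer_overlap,
        gene_ids=gene_ids,
    )


def annotate_regions(
    regions: Iterable[ConsensusRegion], bundle: AnnotationBundle, min_bp: int = 1
) -> List[AnnotatedRegion]:
    return [annotate_region(r, bundle, min_bp) for r in regions]


def promoter_signatures(
    regions: Sequence[ConsensusRegion],
    genes: pd.DataFrame,
    flank: int = 1000,
) -> pd.Series:
    """Per-gene promoter chromatin signature.

    'none' if no promoter of the gene overlaps a categorized region; the
    common category when all marked promoters agree; 'mixed' otherwise.
    Returns a Series indexed by gene_id.
    """
    by_cat: Dict[str, IntervalSet] = {}
    for cat in {r.category for r in regions}:
        by_cat[cat] = IntervalSet(
            r.interval for r in regions if r.category == cat
        ).normalize()
    sig: Dict[str, set] = {g: set() for g in genes["gene_id"].unique()}
    for r in genes.itertuples():
        prom = _promoter_interval(r.chrom, int(r.tss), flank)
        for cat, iset in by_cat.items():
            if iset.overlaps_any(prom):
                sig[r.gene_id].add(cat)
    out = {}
    for gene, cats in sig.items():
        if not cats:
            out[gene] = "none"
        elif len(cats) == 1:
            out[gene] = next(iter(cats))
        else:
            out[gene] = "mixed"
    return pd.Series(out, name="signature").sort_index()


def retroelement_profile(
    tss: pd.DataFrame,
    repeats: Dict[str, IntervalSet],
    window: int = 4000,
    bin_size: int = 100,
    classes: Tuple[str, ...] = ("LINE", "SINE", "LTR"),
) -> pd.DataFrame:
    """Fraction of TSS whose strand-oriented bin overlaps a repeat per class.

    Bins tile [-window, +window) relative to the TSS; negative offsets are
    upstream (strand-aware).  Returns a DataFrame indexed by bin start offset
    with one column per repeat class.
    """
    if window % bin_size != 0:
        raise ValueError("bin_size must divide window evenly")
    offsets = np.arange(-window, window, bin_size)
    counts = {c: np.zeros(len(offsets), dtype=float) for c in classes}
    n_tss = 0
    for r in tss.itertuples():
        n_tss += 1
        t = int(r.tss)
        minus = r.strand == "-"
        for k, off in enumerate(offsets):
            if minus:
                lo, hi = t - (off + bin_size), t - off
            else:
                lo, hi = t + off, t + off + bin_size
            lo = max(0, lo)
            if lo >= hi:
                continue
            q = GenomicInterval(r.chrom, lo, hi)
            for c in classes:
                iset = repeats.get(c)
                if iset is not None and iset.overlaps_any(q):
                    counts[c][k] += 1
    frac = {
        c: (counts[c] / n_tss if n_tss else counts[c]) for c in classes
    }
    return pd.DataFrame(frac, index=pd.Index(offsets, name="offset"))


def feature_class_table(annotated: Sequence[AnnotatedRegion]) -> pd.Series:
    """Region counts per mutually exclusive feature class (partition)."""
    counts = pd.Series(0, index=list(FEATURE_CLASSES), dtype=int)
    for a in annotated:
        counts[a.feature_class] += 1
    return counts
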