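"""Seeded synthetic study generator with planted truth.

Emulates the statistical structure the pipeline assumes so that every stage
is testable without downloads:

* a small genome (5 autosomes x 10 Mb + chrX 5 Mb) with planted bivalent /
  H3K4me3-only / H3K27me3-only regions, CGI/promoter-concentrated bivalency
  and retroelement depletion bordering bivalent TSS;
* five-cell-line peak sets with boundary jitter and per-line dropout
  (dropout creates the line-specific regions seen in real consensus calls);
* four-factor signal tracks with a 3-cluster structure (cluster 1
  PolII/TAF1-high, cluster 2 EZH2-high, cluster 3 intermediate) at
  proportions 17/22/61%;
* methylation-array data (manifest + beta matrix + sample sheet) for eight
  tumor types with hypermethylation planted preferentially at cluster-2
  bivalent CGIs and a pan-cancer recurrent subset;
* a genes x tissues RPKM matrix in which H3K4me3-only genes are expressed
  everywhere, H3K27me3-only genes are silent and bivalent genes switch in a
  tissue-specific, cluster-dependent way.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationBundle
from .intervals import GenomicInterval, IntervalSet, PeakSet
from .signal import SignalTrack

__all__ = [
    "GenomeSpec",
    "PlantedTruth",
    "MethylomeData",
    "simulate_annotations",
    "simulate_peaksets",
    "simulate_tracks",
    "simulate_methylomes",
    "simulate_expression",
    "CELL_LINES",
    "TUMOR_TYPES",
]

CELL_LINES = ("H1", "I3", "HUES6", "HUES48", "HUES64")
TUMOR_TYPES = ("BLCA", "BRCA", "COAD", "HNSC", "KIRP", "LIHC", "LUSC", "LUAD")
CLUSTER_PROPORTIONS = (0.17, 0.22, 0.61)  # observed bivalent-promoter ratios

# fraction of regions whose center is a gene TSS (promoter-associated) and,
# of those, the fraction whose promoter sits in a CGI — chosen to mirror the
# observed 75/74/24.5% promoter and 71/61/1.5% CGI-promoter proportions
PROMOTER_FRAC = {"bivalent": 0.75, "K4only": 0.74, "K27only": 0.245}
CGI_GIVEN_PROMOTER = {"bivalent": 0.947, "K4only": 0.824, "K27only": 0.061}


@dataclass
class GenomeSpec:
    """Synthetic genome layout and scale."""

    chroms: Dict[str, int] = field(
        default_factory=lambda: {
            **{f"chr{i}": 10_000_000 for i in range(1, 6)},
            "chrX": 5_000_000,
        }
    )
    n_bivalent: int = 200
    n_bivalent_x: int = 10
    n_k4only: int = 200
    n_k27only: int = 200
    n_none_cgi: int = 100
    n_genes: int = 1200
    cgi_promoter_frac: float = 0.6
    repeat_density: float = 0.25
    repeat_depletion: float = 0.3  # keep-probability of a repeat near a bivalent TSS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chroms.values()):
            raise ValueError("chromosome lengths must be positive")
        for frac in (self.cgi_promoter_frac, self.repeat_density, self.repeat_depletion):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``regions``: one row per planted region (region_id, chrom, start, end,
    category, cluster, has_gene, gene_id, is_cgi).  ``genes``: one row per
    TSS (gene_id, chrom, tss, strand, start, end, expr_class, cluster).
    Methylation truth is attached by :func:`simulate_methylomes`.
    """

    regions: pd.DataFrame
    genes: pd.DataFrame
    seed: int
    hyper: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict)
    hypo: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict)
    pan_cancer: Dict[str, Set[str]] = field(default_factory=dict)

    def regions_by_category(self, category: str, autosomal_only: bool = True) -> pd.DataFrame:
        df = self.regions[self.regions["category"] == category]
        if autosomal_only:
            df = df[~df["chrom"].isin(["chrX", "chrY"])]
        return df


@dataclass
class MethylomeData:
    manifest: pd.DataFrame
    beta: pd.DataFrame
    samples: pd.DataFrame


# --------------------------------------------------------------------------- #
# annotations + planted regions
# --------------------------------------------------------------------------- #
def _slot_positions(spec: GenomeSpec, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Candidate region centers, >= 30 kb apart, per chromosome."""
    slots = {}
    for chrom, length in spec.chroms.items():
        centers = np.arange(60_000, length - 60_000, 30_000)
        rng.shuffle(centers)
        slots[chrom] = centers
    return slots


def simulate_annotations(spec: GenomeSpec) -> Tuple[AnnotationBundle, PlantedTruth]:
    """Plant regions, genes, CGIs, repeats and enhancers; return bundle + truth."""
    rng = np.random.default_rng(spec.seed)
    slots = _slot_positions(spec, rng)
    autosomes = [c for c in spec.chroms if c not in ("chrX", "chrY")]
    pool: List[Tuple[str, int]] = [
        (c, int(p)) for c in autosomes for p in slots[c]
    ]
    rng.shuffle(pool)
    x_pool = [("chrX", int(p)) for p in slots.get("chrX", [])]

    rows = []
    counter = 0

    def plant(n: int, category: str, source: List[Tuple[str, int]]) -> None:
        nonlocal counter
        for _ in range(n):
            chrom, center = source.pop()
            width = int(rng.integers(1200, 3001))
            start = center - width // 2
            counter += 1
            rows.append(
                {
                    "region_id": f"T{counter:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + width,
                    "category": category,
                }
            )

    plant(spec.n_bivalent, "bivalent", pool)
    plant(spec.n_k4only, "K4only", pool)
    plant(spec.n_k27only, "K27only", pool)
    plant(spec.n_none_cgi, "none", pool)
    plant(spec.n_bivalent_x, "bivalent", x_pool)
    regions = pd.DataFrame(rows)

    # cluster labels for bivalent regions
    clusters = np.full(len(regions), np.nan)
    biv = regions["category"] == "bivalent"
    clusters[biv.to_numpy()] = rng.choice(
        [1, 2, 3], size=int(biv.sum()), p=CLUSTER_PROPORTIONS
    )
    regions["cluster"] = clusters

    # genes: one TSS at the center of a fraction of regions, plus background
    gene_rows = []
    gid = 0
    region_gene: List[Optional[str]] = []
    for row in regions.itertuples():
        p = PROMOTER_FRAC.get(row.category, 0.5 if row.category == "none" else 0.0)
        if rng.random() < p:
            gid += 1
            gene_id = f"G{gid:05d}"
            tss = (row.start + row.end) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            body = int(rng.integers(5_000, 40_000))
            start = tss if strand == "+" else max(0, tss - body)
            end = tss + body if strand == "+" else tss + 1
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": row.chrom,
                    "tss": int(tss),
                    "strand": strand,
                    "start": int(start),
                    "end": int(end),
                    "expr_class": row.category,
                    "cluster": row.cluster,
                }
            )
            region_gene.append(gene_id)
        else:
            region_gene.append(None)
    regions["gene_id"] = region_gene
    regions["has_gene"] = regions["gene_id"].notna()

    # a few multi-promoter genes: same-category pairs stay classed, mixed
    # pairs become 'mixed' (excluded downstream)
    genes = pd.DataFrame(gene_rows)
    _merge_multipromoter_genes(genes, regions, rng)

    # background genes away from planted regions
    n_bg = max(0, spec.n_genes - genes["gene_id"].nunique())
    for _ in range(n_bg):
        if not pool:
            break
        chrom, center = pool.pop()
        gid += 1
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(5_000, 40_000))
        start = center if strand == "+" else max(0, center - body)
        end = center + body if strand == "+" else center + 1
        genes.loc[len(genes)] = {
            "gene_id": f"G{gid:05d}",
            "chrom": chrom,
            "tss": int(center),
            "strand": strand,
            "start": int(start),
            "end": int(end),
            "expr_class": "none",
            "cluster": np.nan,
        }

    # CGIs
    cgi_ivs = []
    is_cgi = []
    for row in regions.itertuples():
        if row.category == "none":
            cgi = True  # planted unmarked CGIs ("none-regions")
        elif row.has_gene:
            cgi = rng.random() < CGI_GIVEN_PROMOTER.get(row.category, 0.0)
        else:
            cgi = False
        is_cgi.append(cgi)
        if cgi:
            center = (row.start + row.end) // 2
            cgi_ivs.append(GenomicInterval(row.chrom, center - 600, center + 600))
    regions["is_cgi"] = is_cgi
    bg_genes = genes[genes["expr_class"] == "none"]
    for row in bg_genes.itertuples():
        if rng.random() < spec.cgi_promoter_frac:
            cgi_ivs.append(
                GenomicInterval(row.chrom, max(0, row.tss - 600), row.tss + 600)
            )
    cgis = IntervalSet(cgi_ivs).normalize()

    # repeats: uniform placement, thinned near TSS (most strongly at bivalent TSS)
    repeats = _simulate_repeats(spec, regions, genes, rng)

    # enhancers: overlap 39% / 30% of non-promoter bivalent / K4only regions,
    # plus background enhancers away from promoters
    enh_ivs = []
    enh_frac = {"bivalent": 0.39, "K4only": 0.30}
    for row in regions.itertuples():
        if not row.has_gene and rng.random() < enh_frac.get(row.category, 0.0):
            enh_ivs.append(GenomicInterval(row.chrom, row.start - 200, row.end + 200))
    for _ in range(300):
        if not pool:
            break
        chrom, center = pool.pop()
        enh_ivs.append(GenomicInterval(chrom, center - 200, center + 200))
    enhancers = IntervalSet(enh_ivs).normalize()

    bundle = AnnotationBundle(
        genes=genes[["gene_id", "chrom", "tss", "strand", "start", "end"]].copy(),
        cgis=cgis,
        repeats=repeats,
        enhancers=enhancers,
    )
    truth = PlantedTruth(regions=regions, genes=genes, seed=spec.seed)
    return bundle, truth


def _merge_multipromoter_genes(
    genes: pd.DataFrame, regions: pd.DataFrame, rng: np.random.Generator
) -> None:
    """Turn some gene pairs on the same chromosome into two-TSS genes."""
    marked = regions[regions["has_gene"] & (regions["category"] != "none")]
    for same_category, n_pairs in ((True, 6), (False, 4)):
        for _ in range(n_pairs):
            for chrom in rng.permutation(marked["chrom"].unique()):
                sub = marked[marked["chrom"] == chrom]
                cats = sub["category"].unique()
                if same_category:
                    cands = sub[sub["category"] == cats[0]]
                    if len(cands) < 2:
                        continue
                    pick = cands.sample(2, random_state=int(rng.integers(2**31)))
                else:
                    if len(cats) < 2:
                        continue
                    a = sub[sub["category"] == cats[0]].sample(
                        1, random_state=int(rng.integers(2**31))
                    )
                    b = sub[sub["category"] == cats[1]].sample(
                        1, random_state=int(rng.integers(2**31))
                    )
                    pick = pd.concat([a, b])
                keep_id, drop_id = pick["gene_id"].tolist()
                if keep_id == drop_id:
                    continue
                genes.loc[genes["gene_id"] == drop_id, "gene_id"] = keep_id
                cls = (
                    pick["category"].iloc[0]
                    if pick["category"].nunique() == 1
                    else "mixed"
                )
                genes.loc[genes["gene_id"] == keep_id, "expr_class"] = cls
                marked = marked[~marked["region_id"].isin(pick["region_id"])]
                break


def _simulate_repeats(
    spec: GenomeSpec,
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> Dict[str, IntervalSet]:
    class_probs = {"LINE": 0.30, "SINE": 0.35, "LTR": 0.20, "other": 0.15}
    mean_len = {"LINE": 3000, "SINE": 300, "LTR": 1000, "other": 500}
    genome_len = sum(spec.chroms.values())
    avg_len = sum(class_probs[c] * mean_len[c] for c in class_probs)
    n_repeats = int(spec.repeat_density * genome_len / avg_len)

    biv_tss = genes.merge(
        regions.loc[regions["category"] == "bivalent", ["gene_id"]], on="gene_id"
    )[["chrom", "tss"]]
    biv_tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy()) for c, g in biv_tss.groupby("chrom")
    }
    all_tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")
    }

    def near(sorted_pos: np.ndarray, lo: int, hi: int) -> bool:
        i = np.searchsorted(sorted_pos, lo)
        return i < len(sorted_pos) and sorted_pos[i] < hi

    chrom_names = list(spec.chroms)
    lengths = np.array([spec.chroms[c] for c in chrom_names], dtype=float)
    chrom_p = lengths / lengths.sum()
    out: Dict[str, List[GenomicInterval]] = {c: [] for c in class_probs}
    classes = list(class_probs)
    cls_p = np.array([class_probs[c] for c in classes])
    for _ in range(n_repeats):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        cls = classes[int(rng.choice(len(classes), p=cls_p))]
        length = max(80, int(rng.exponential(mean_len[cls])))
        start = int(rng.integers(0, spec.chroms[chrom] - length))
        lo, hi = start - 1000, start + length + 1000
        keep = 1.0
        if near(biv_tss_by_chrom.get(chrom, np.empty(0)), lo, hi):
            keep = spec.repeat_depletion
        elif near(all_tss_by_chrom.get(chrom, np.empty(0)), lo, hi):
            keep = 0.7
        if rng.random() < keep:
            out[cls].append(GenomicInterval(chrom, start, start + length))
    return {c: IntervalSet(ivs).normalize() for c, ivs in out.items()}


# --------------------------------------------------------------------------- #
# peak sets
# --------------------------------------------------------------------------- #
def simulate_peaksets(
    truth: PlantedTruth,
    n_lines: int = 5,
    jitter_sd: float = 0.0,
    dropout: float = 0.0,
    seed: Optional[int] = None,
) -> Dict[str, Dict[str, PeakSet]]:
    """Per-line H3K4me3/H3K27me3 peak sets around the planted regions.

    Bivalent regions emit an H3K4me3 peak equal to the region and an
    H3K27me3 peak extended 1 kb both ways (their overlap is the region);
    dropout removes a bivalent region from a line entirely, creating
    line-specific regions.  Single-mark regions emit their mark in every
    line.  Boundary jitter is Gaussian with SD ``jitter_sd`` bp.
    """
    if jitter_sd < 0 or not (0 <= dropout < 1):
        raise ValueError("jitter_sd must be >= 0 and dropout in [0, 1)")
    rng = np.random.default_rng(truth.seed + 101 if seed is None else seed)
    lines = list(CELL_LINES[:n_lines])

    def jit(pos: int) -> int:
        return max(0, int(round(pos + rng.normal(0.0, jitter_sd)))) if jitter_sd else pos

    out: Dict[str, Dict[str, PeakSet]] = {"H3K4me3": {}, "H3K27me3": {}}
    for line in lines:
        k4_ivs: List[GenomicInterval] = []
        k27_ivs: List[GenomicInterval] = []
        for row in truth.regions.itertuples():
            if row.category == "bivalent":
                if dropout and rng.random() < dropout:
                    continue
                k4_ivs.append(
                    GenomicInterval(row.chrom, jit(row.start), jit(row.end))
                )
                k27_ivs.append(
                    GenomicInterval(
                        row.chrom, jit(row.start - 1000), jit(row.end + 1000)
                    )
                )
            elif row.category == "K4only":
                k4_ivs.append(GenomicInterval(row.chrom, jit(row.start), jit(row.end)))
            elif row.category == "K27only":
                k27_ivs.append(GenomicInterval(row.chrom, jit(row.start), jit(row.end)))
        out["H3K4me3"][line] = PeakSet(line, "H3K4me3", k4_ivs)
        out["H3K27me3"][line] = PeakSet(line, "H3K27me3", k27_ivs)
    return out


# --------------------------------------------------------------------------- #
# factor signal tracks
# --------------------------------------------------------------------------- #
# mean bump amplitudes (reads) per cluster; cluster 1 is PolII/TAF1-high,
# cluster 2 EZH2-high (TCF12 intermediate), cluster 3 uniformly intermediate
CLUSTER_AMPS = {
    1: {"EZH2": 10.0, "PolII": 120.0, "TAF1": 120.0, "TCF12": 10.0},
    2: {"EZH2": 120.0, "PolII": 10.0, "TAF1": 10.0, "TCF12": 70.0},
    3: {"EZH2": 40.0, "PolII": 40.0, "TAF1": 40.0, "TCF12": 40.0},
}


def simulate_tracks(
    truth: PlantedTruth,
    seed: Optional[int] = None,
    amp_scale: float = 1.0,
    within_sd: float = 0.4,
    background: float = 0.001,
    bin_size: int = 100,
) -> Dict[str, SignalTrack]:
    """Four-factor coverage tracks with cluster-dependent bump amplitudes.

    ``amp_scale`` in [0, 1] interpolates the per-cluster amplitudes toward
    their common geometric mean (0 = clusters indistinguishable);
    ``within_sd`` is the within-cluster log2 SD of region amplitudes.
    """
    rng = np.random.default_rng(truth.seed + 202 if seed is None else seed)
    factors = ("EZH2", "PolII", "TAF1", "TCF12")
    log_mean = {
        f: np.mean([np.log2(CLUSTER_AMPS[c][f]) for c in (1, 2, 3)]) for f in factors
    }
    biv = truth.regions[truth.regions["category"] == "bivalent"]
    runs: Dict[str, Dict[str, List[Tuple[int, int, float]]]] = {
        f: {} for f in factors
    }
    for row in biv.itertuples():
        cluster = int(row.cluster)
        center = (row.start + row.end) // 2
        bump_lo, bump_hi = center - 800, center + 800
        win_lo, win_hi = max(0, row.start - 6000), row.end + 6000
        for f in factors:
            log_amp = (
                log_mean[f]
                + amp_scale * (np.log2(CLUSTER_AMPS[cluster][f]) - log_mean[f])
                + rng.normal(0.0, within_sd)
            )
            amp = float(2.0**log_amp)
            chrom_runs = runs[f].setdefault(row.chrom, [])
            # background bins across the window, bump value inside the core
            for lo in range(win_lo, win_hi, bin_size):
                hi = min(lo + bin_size, win_hi)
                val = rng.poisson(background * bin_size) / bin_size
                if lo < bump_hi and hi > bump_lo:
                    val += amp / (bump_hi - bump_lo)
                if val > 0:
                    chrom_runs.append((lo, hi, val))
    tracks = {}
    for f in factors:
        data = {
            chrom: (
                np.array([r[0] for r in rs]),
                np.array([r[1] for r in rs]),
                np.array([r[2] for r in rs]),
            )
            for chrom, rs in runs[f].items()
        }
        tracks[f] = SignalTrack(data)
    return tracks


# --------------------------------------------------------------------------- #
# methylomes
# --------------------------------------------------------------------------- #
def simulate_methylomes(
    truth: PlantedTruth,
    n_pairs: int = 20,
    n_types: int = 8,
    effect: float = 0.4,
    noise_sd: float = 0.05,
    n_probes: int = 20_000,
    n_hyper_pos: int = 400,
    n_hyper_neg: int = 120,
    n_hypo_pos: int = 40,
    pan_pos: int = 80,
    pan_neg: int = 25,
    seed: Optional[int] = None,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> MethylomeData:
    """Array manifest, beta matrix and sample sheet for ``n_types`` tumor types.

    Hypermethylation (+``effect`` on the beta scale) is planted in tumors,
    preferentially at cluster-2 bivalent CGI probes (70% of each planted
    set); a pan-cancer subset recurs in >= 5 types.  Planted truth sets are
    recorded on ``truth.hyper`` / ``truth.hypo`` / ``truth.pan_cancer``.
    """
    if not 0 < effect < 1:
        raise ValueError("effect must lie in (0, 1)")
    rng = np.random.default_rng(truth.seed + 303 if seed is None else seed)
    types = list(TUMOR_TYPES[:n_types])

    # ---------------- manifest ----------------
    probes_per = {"bivalent": 8, "K4only": 6, "K27only": 3, "none": 5}
    rows = []
    pid = 0
    for row in truth.regions.itertuples():
        n = probes_per[row.category]
        width = row.end - row.start
        offsets = np.sort(rng.choice(width, size=min(n, width), replace=False))
        for off in offsets:
            pid += 1
            if row.has_gene:
                feature = "promoter"
            else:
                feature = "gene body" if rng.random() < 0.5 else "intergenic"
            rows.append(
                {
                    "probe_id": f"cg{pid:08d}",
                    "chrom": row.chrom,
                    "position": int(row.start + off),
                    "cgi_relation": "Island" if row.is_cgi else "open sea",
                    "feature": feature,
                    "region_id": row.region_id,
                    "region_category": row.category,
                    "region_cluster": row.cluster,
                    "region_is_cgi": row.is_cgi,
                }
            )
    # background probes outside planted regions
    lengths = chrom_lengths or {
        c: int(truth.regions.loc[truth.regions["chrom"] == c, "end"].max() + 100_000)
        for c in truth.regions["chrom"].unique()
    }
    region_set = IntervalSet(
        GenomicInterval(r.chrom, r.start, r.end) for r in truth.regions.itertuples()
    ).normalize()
    chroms = list(lengths)
    lens = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_p = lens / lens.sum()
    while pid < n_probes:
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        pos = int(rng.integers(0, lengths[chrom]))
        if region_set.overlaps_any(GenomicInterval(chrom, pos, pos + 1)):
            continue
        pid += 1
        feature = rng.choice(["promoter", "gene body", "intergenic"], p=[0.3, 0.4, 0.3])
        rows.append(
            {
                "probe_id": f"cg{pid:08d}",
                "chrom": chrom,
                "position": pos,
                "cgi_relation": rng.choice(
                    ["N_Shore", "S_Shore", "open sea"], p=[0.15, 0.15, 0.7]
                ),
                "feature": feature,
                "region_id": None,
                "region_category": "none",
                "region_cluster": np.nan,
                "region_is_cgi": False,
            }
        )
    manifest = pd.DataFrame(rows)

    # ---------------- baselines ----------------
    base = np.full(len(manifest), 0.5)
    cat = manifest["region_category"].to_numpy()
    feat = manifest["feature"].to_numpy()
    in_region = manifest["region_id"].notna().to_numpy()
    base[(cat == "K4only")] = 0.05
    base[(cat == "bivalent")] = 0.07
    base[(cat == "K27only")] = 0.78
    none_cgi = in_region & (cat == "none")
    base[none_cgi & (feat == "promoter")] = 0.07
    base[none_cgi & (feat != "promoter")] = 0.80
    # a minority of bivalent probes are already methylated in the normal state
    biv_idx = np.nonzero(cat == "bivalent")[0]
    already = rng.choice(biv_idx, size=int(0.12 * len(biv_idx)), replace=False)
    base[already] = 0.45
    base = np.clip(base + rng.normal(0.0, 0.015, size=len(base)), 0.02, 0.98)
    manifest["baseline"] = base

    # ---------------- planted call sets ----------------
    low = base < 0.5
    pools = {
        "c2": manifest.index[
            (cat == "bivalent")
            & (manifest["region_cluster"] == 2)
            & manifest["region_is_cgi"].to_numpy()
            & low
        ],
        "c3": manifest.index[(cat == "bivalent") & (manifest["region_cluster"] == 3) & low],
        "c1": manifest.index[(cat == "bivalent") & (manifest["region_cluster"] == 1) & low],
        "none": manifest.index[none_cgi & (feat == "promoter") & low],
        "k4": manifest.index[(cat == "K4only") & low],
    }
    composition = (("c2", 0.70), ("c3", 0.12), ("c1", 0.05), ("none", 0.10), ("k4", 0.03))
    probe_ids = manifest["probe_id"].to_numpy()

    def sample_set(n: int) -> Set[str]:
        chosen: List[int] = []
        for pool_name, frac in composition:
            pool = pools[pool_name]
            k = min(int(round(frac * n)), len(pool))
            if k:
                chosen.extend(rng.choice(pool, size=k, replace=False))
        return {probe_ids[i] for i in chosen}

    pan_pos_set = sample_set(pan_pos)
    pan_neg_set = sample_set(pan_neg)
    pan_pos_types = set(rng.choice(types, size=min(6, len(types)), replace=False))
    pan_neg_types = set(rng.choice(types, size=min(5, len(types)), replace=False))
    truth.pan_cancer = {"positive": pan_pos_set, "negative": pan_neg_set}

    high_body = manifest.index[none_cgi & (feat != "promoter")]
    for t in types:
        hyper_pos = sample_set(n_hyper_pos)
        if t in pan_pos_types:
            hyper_pos |= pan_pos_set
        hyper_neg = sample_set(n_hyper_neg)
        if t in pan_neg_types:
            hyper_neg |= pan_neg_set
        truth.hyper[(t, "positive")] = hyper_pos
        truth.hyper[(t, "negative")] = hyper_neg
        hypo_idx = rng.choice(high_body, size=min(n_hypo_pos, len(high_body)), replace=False)
        truth.hypo[(t, "positive")] = {probe_ids[i] for i in hypo_idx}
        truth.hypo[(t, "negative")] = set()

    # ---------------- samples + beta ----------------
    sample_rows = []
    for t in types:
        for i in range(n_pairs):
            pair = f"{t}_P{i:02d}"
            cimp = "positive" if i < n_pairs // 2 else "negative"
            if t == types[0] and i >= n_pairs - 2:
                cimp = "NA"  # a couple of unclassifiable tumors
            sample_rows.append(
                {
                    "sample_id": f"{t}_T{i:02d}",
                    "tumor_type": t,
                    "status": "tumor",
                    "pair_id": pair,
                    "cimp": cimp,
                }
            )
            sample_rows.append(
                {
                    "sample_id": f"{t}_N{i:02d}",
                    "tumor_type": t,
                    "status": "normal",
                    "pair_id": pair,
                    "cimp": "NA",
                }
            )
    samples = pd.DataFrame(sample_rows)

    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    beta = np.empty((len(manifest), len(samples)))
    for j, srow in enumerate(samples.itertuples()):
        mu = base.copy()
        if srow.status == "tumor" and srow.cimp in ("positive", "negative"):
            for p in truth.hyper.get((srow.tumor_type, srow.cimp), ()):
                mu[probe_pos[p]] += effect
            for p in truth.hypo.get((srow.tumor_type, srow.cimp), ()):
                mu[probe_pos[p]] -= effect
        beta[:, j] = np.clip(mu + rng.normal(0.0, noise_sd, size=len(mu)), 0.0, 1.0)
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=samples["sample_id"].to_numpy())
    return MethylomeData(manifest=manifest, beta=beta_df, samples=samples)


# --------------------------------------------------------------------------- #
# expression
# --------------------------------------------------------------------------- #
def simulate_expression(
    truth: PlantedTruth,
    n_tissues: int = 34,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Genes x tissues RPKM with class- and cluster-dependent behavior.

    H3K4me3-only genes: high in every tissue; H3K27me3-only: silent;
    bivalent: per-tissue on/off switching with cluster-dependent on-rates
    (cluster 1 mostly on, cluster 2 mostly off).
    """
    rng = np.random.default_rng(truth.seed + 404 if seed is None else seed)
    tissues = [f"tissue{i:02d}" for i in range(1, n_tissues + 1)]
    genes = truth.genes.drop_duplicates("gene_id").set_index("gene_id")
    log2 = np.empty((len(genes), n_tissues))
    on_rate = {1: 0.80, 2: 0.12, 3: 0.50}
    on_level = {1: 4.5, 2: 3.0, 3: 3.5}
    for i, (gene_id, row) in enumerate(genes.iterrows()):
        cls = row["expr_class"]
        if cls == "K4only":
            log2[i] = rng.normal(5.0, 0.7, n_tissues)
        elif cls == "K27only":
            log2[i] = rng.normal(-6.0, 0.7, n_tissues)
        elif cls == "bivalent":
            c = int(row["cluster"]) if np.isfinite(row["cluster"]) else 3
            on = rng.random(n_tissues) < on_rate[c]
            log2[i] = np.where(
                on,
                rng.normal(on_level[c], 0.7, n_tissues),
                rng.normal(-3.0, 0.7, n_tissues),
            )
        else:  # none / mixed background behavior
            log2[i] = rng.normal(1.5, 1.2, n_tissues)
    rpkm = pd.DataFrame(2.0**log2, index=genes.index, columns=tissues)
    return rpkm
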