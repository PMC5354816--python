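"""File readers and writers for the pipeline's external dialects.

BED-family files are 0-based half-open; Illumina manifest positions
(MAPINFO) are 1-based and converted to 0-based on read.  Chromosome names
are normalized to the "chr" form at every reader.  All tabular outputs are
plain TSV; the genome-browser export is BED9 with the category palette
(bivalent black, H3K4me3-only blue, H3K27me3-only purple).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .annotation import AnnotatedRegion, AnnotationBundle
from .domains import ConsensusRegion
from .intervals import GenomicInterval, IntervalSet, InvalidIntervalError, PeakSet

__all__ = [
    "normalize_chrom",
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_genes_bed",
    "write_genes_bed",
    "read_class_bed",
    "read_bed",
    "write_bed",
    "read_manifest",
    "write_manifest",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_expression",
    "write_expression",
    "write_region_table",
    "read_region_table",
    "write_browser_track",
    "write_array_annotation",
    "load_config",
    "file_checksum",
    "BROWSER_PALETTE",
]

PathLike = Union[str, Path]

BROWSER_PALETTE = {
    "bivalent": "0,0,0",
    "K4only": "0,0,255",
    "K27only": "128,0,128",
}


def normalize_chrom(name: str) -> str:
    """Normalize chromosome dialects ('1', 'chr1', 'CHR1') to 'chr1'."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


# --------------------------------------------------------------------------- #
# BED family
# --------------------------------------------------------------------------- #
def _parse_bed_line(line: str, path: PathLike, lineno: int, min_cols: int) -> List[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise ValueError(
            f"{path}:{lineno}: expected >= {min_cols} tab-separated columns, got {len(fields)}"
        )
    return fields


def read_bed(path: PathLike, min_cols: int = 3) -> List[List[str]]:
    """Raw BED records (list of column lists), skipping track/browser headers."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            records.append(_parse_bed_line(line, path, lineno, min_cols))
    return records


def write_bed(path: PathLike, rows: Iterable[Sequence], header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_peaks(
    path: PathLike,
    cell_line: str,
    mark: str,
    dialect: Optional[str] = None,
) -> PeakSet:
    """Read a peak file as a PeakSet.

    ``dialect``: 'bed', 'narrowPeak' or 'broadPeak'; inferred from the file
    suffix when omitted.  narrowPeak/broadPeak column 9 (-log10 q-value) is
    converted to an FDR (10**-q).
    """
    if dialect is None:
        suffix = str(path).lower()
        if suffix.endswith(".narrowpeak"):
            dialect = "narrowPeak"
        elif suffix.endswith(".broadpeak"):
            dialect = "broadPeak"
        else:
            dialect = "bed"
    if dialect not in ("bed", "narrowPeak", "broadPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    min_cols = {"bed": 3, "narrowPeak": 10, "broadPeak": 9}[dialect]
    peaks: List[GenomicInterval] = []
    scores: List[float] = []
    fdrs: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = _parse_bed_line(line, path, lineno, min_cols)
            try:
                iv = GenomicInterval(
                    normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
                )
            except (ValueError, InvalidIntervalError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from exc
            peaks.append(iv)
            if dialect != "bed":
                scores.append(float(fields[4]))
                neglog_q = float(fields[8])
                fdrs.append(10.0 ** (-neglog_q) if neglog_q >= 0 else float("nan"))
    return PeakSet(
        cell_line,
        mark,
        peaks,
        score=scores or None,
        fdr=fdrs or None,
    )


def write_peaks(path: PathLike, peakset: PeakSet, dialect: str = "bed") -> None:
    rows = []
    for i, iv in enumerate(peakset.peaks):
        if dialect == "bed":
            rows.append((iv.chrom, iv.start, iv.end))
        elif dialect == "narrowPeak":
            score = peakset.score[i] if peakset.score else 0
            fdr = peakset.fdr[i] if peakset.fdr else 1.0
            neglog_q = -np.log10(max(fdr, 1e-300))
            rows.append(
                (iv.chrom, iv.start, iv.end, f"peak{i+1}", score, ".", 0, 0, f"{neglog_q:.10g}", -1)
            )
        else:
            raise ValueError(f"unsupported write dialect {dialect!r}")
    write_bed(path, rows)


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    """4-column bedGraph (chrom, start, end, value), 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = _parse_bed_line(line, path, lineno, 4)
            rows.append(
                (normalize_chrom(fields[0]), int(fields[1]), int(fields[2]), float(fields[3]))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(path: PathLike, df: pd.DataFrame) -> None:
    out = df.sort_values(["chrom", "start"])
    write_bed(
        path,
        ((r.chrom, r.start, r.end, f"{r.value:g}") for r in out.itertuples()),
    )


def read_genes_bed(path: PathLike) -> pd.DataFrame:
    """Gene/TSS table from BED6+ (chrom, start, end, gene_id, score, strand).

    The TSS is the strand-aware 5' end (start for '+', end-1 for '-'); one
    row per record, so multi-TSS genes simply repeat the gene_id.
    """
    rows = []
    for fields in read_bed(path, min_cols=6):
        chrom = normalize_chrom(fields[0])
        start, end = int(fields[1]), int(fields[2])
        strand = fields[5]
        tss = start if strand == "+" else end - 1
        rows.append(
            {
                "gene_id": fields[3],
                "chrom": chrom,
                "tss": tss,
                "strand": strand,
                "start": start,
                "end": end,
            }
        )
    return pd.DataFrame(rows)


def write_genes_bed(path: PathLike, genes: pd.DataFrame) -> None:
    rows = []
    for r in genes.itertuples():
        rows.append((r.chrom, r.start, r.end, r.gene_id, 0, r.strand))
    write_bed(path, rows)


def read_class_bed(path: PathLike) -> Dict[str, IntervalSet]:
    """BED4 where the name column is a class label (RepeatMasker-style)."""
    by_class: Dict[str, List[GenomicInterval]] = {}
    for fields in read_bed(path, min_cols=4):
        by_class.setdefault(fields[3], []).append(
            GenomicInterval(normalize_chrom(fields[0]), int(fields[1]), int(fields[2]))
        )
    return {c: IntervalSet(ivs).normalize() for c, ivs in by_class.items()}


def read_plain_bed(path: PathLike) -> IntervalSet:
    return IntervalSet(
        GenomicInterval(normalize_chrom(f[0]), int(f[1]), int(f[2]))
        for f in read_bed(path, min_cols=3)
    ).normalize()


# --------------------------------------------------------------------------- #
# array manifest / beta matrix / sample sheet / expression
# --------------------------------------------------------------------------- #
MANIFEST_COLUMNS = [
    "TargetID",
    "CHR",
    "MAPINFO",
    "UCSC_REFGENE_GROUP",
    "RELATION_TO_UCSC_CPG_ISLAND",
]

_FEATURE_TO_REFGENE = {"promoter": "TSS200", "gene body": "Body", "intergenic": ""}
_REFGENE_TO_FEATURE = {"TSS200": "promoter", "TSS1500": "promoter", "Body": "gene body"}


def write_manifest(path: PathLike, manifest: pd.DataFrame) -> None:
    """Write the internal manifest frame in the Illumina-style TSV dialect."""
    out = pd.DataFrame(
        {
            "TargetID": manifest["probe_id"],
            "CHR": manifest["chrom"].map(lambda c: str(c)[3:] if str(c).startswith("chr") else c),
            "MAPINFO": manifest["position"].astype(int) + 1,  # 1-based on disk
            "UCSC_REFGENE_GROUP": manifest["feature"].map(_FEATURE_TO_REFGENE),
            "RELATION_TO_UCSC_CPG_ISLAND": manifest["cgi_relation"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return pd.DataFrame(
        {
            "probe_id": df["TargetID"],
            "chrom": df["CHR"].map(normalize_chrom),
            "position": df["MAPINFO"].astype(int) - 1,  # to 0-based
            "feature": df["UCSC_REFGENE_GROUP"].map(
                lambda g: _REFGENE_TO_FEATURE.get(g, "intergenic")
            ),
            "cgi_relation": df["RELATION_TO_UCSC_CPG_ISLAND"],
        }
    )


def write_beta_matrix(path: PathLike, beta: pd.DataFrame) -> None:
    beta.to_csv(path, sep="\t", index_label="TargetID", float_format="%.6g")


def read_beta_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="TargetID")


SAMPLE_SHEET_COLUMNS = ["Sample_ID", "Type", "Status", "Pair_ID", "CIMP"]


def write_sample_sheet(path: PathLike, samples: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "Sample_ID": samples["sample_id"],
            "Type": samples["tumor_type"],
            "Status": samples["status"],
            "Pair_ID": samples["pair_id"],
            "CIMP": samples["cimp"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns {missing}")
    return pd.DataFrame(
        {
            "sample_id": df["Sample_ID"],
            "tumor_type": df["Type"],
            "status": df["Status"],
            "pair_id": df["Pair_ID"],
            "cimp": df["CIMP"],
        }
    )


def write_expression(path: PathLike, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# --------------------------------------------------------------------------- #
# region table / browser track / array annotation
# --------------------------------------------------------------------------- #
REGION_TABLE_COLUMNS = [
    "region_id",
    "chrom",
    "start",
    "end",
    "width",
    "category",
    "n_lines_support",
    "supporting_lines",
    "is_cgi",
    "is_promoter",
    "is_cgi_promoter",
    "feature_class",
    "enhancer_overlap",
    "gene_ids",
    "cluster",
]


def write_region_table(
    path: PathLike, annotated: Sequence[AnnotatedRegion]
) -> None:
    """The full annotated HC-region list (coordinates, gene, main features)."""
    rows = []
    for a in annotated:
        r = a.region
        iv = r.interval
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "width": iv.width,
                "category": r.category,
                "n_lines_support": r.n_lines,
                "supporting_lines": ",".join(sorted(r.supporting_lines)),
                "is_cgi": int(a.is_cgi),
                "is_promoter": int(a.is_promoter),
                "is_cgi_promoter": int(a.is_cgi_promoter),
                "feature_class": a.feature_class,
                "enhancer_overlap": int(a.enhancer_overlap),
                "gene_ids": ",".join(a.gene_ids),
                "cluster": "" if r.cluster is None else int(r.cluster),
            }
        )
    df = pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS)
    df = df.sort_values(["chrom", "start", "end"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_region_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_browser_track(
    path: PathLike,
    annotated: Sequence[AnnotatedRegion],
    name: str = "hESC chromatin signature",
) -> None:
    """BED9 browser track, itemRgb on, fixed category palette."""
    header = f'track name="{name}" itemRgb="On"'
    rows = []
    for a in sorted(
        annotated, key=lambda a: (a.region.interval.chrom, a.region.interval.start)
    ):
        iv = a.region.interval
        rgb = BROWSER_PALETTE.get(a.region.category, "128,128,128")
        rows.append(
            (iv.chrom, iv.start, iv.end, a.region.region_id, 0, ".", iv.start, iv.end, rgb)
        )
    write_bed(path, rows, header=header)


ARRAY_ANNOTATION_HEADER = ["TargetID", "ChromatinState", "BivalentCluster", "RegionID"]
_STATE_NAMES = {
    "none": "None",
    "bivalent": "Bivalent",
    "K4only": "H3K4me3only",
    "K27only": "H3K27me3only",
}


def write_array_annotation(path: PathLike, probe_categories: pd.DataFrame) -> None:
    """GenomeStudio-ready per-probe chromatin annotation (one row per probe)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ARRAY_ANNOTATION_HEADER) + "\n")
        for probe_id, row in probe_categories.iterrows():
            state = _STATE_NAMES[row["category"]]
            cluster = (
                str(int(row["cluster"])) if pd.notna(row["cluster"]) else "NA"
            )
            region = row["region_id"] if row["region_id"] else "NA"
            fh.write(f"{probe_id}\t{state}\t{cluster}\t{region}\n")


# --------------------------------------------------------------------------- #
# config / checksums
# --------------------------------------------------------------------------- #
def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def file_checksum(path: PathLike) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
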