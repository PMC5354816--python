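"""End-to-end pipeline orchestration over the library modules.

Each step reads its inputs from paths in a config mapping, computes with the
library, and writes plain-text outputs under ``outdir``.  The steps are
deliberately thin — all science lives in the per-stage modules — and fully
deterministic under a fixed config + seed (no timestamps in any output).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    AnnotatedRegion,
    AnnotationBundle,
    annotate_regions,
    promoter_signatures,
    retroelement_profile,
)
from .domains import ConsensusRegion, build_hc_lists
from .expression import (
    class_expression_summary,
    cluster_expression_medians,
    iqr_by_gene,
    normalize_to_k4,
)
from .intervals import GenomicInterval
from .methylation import (
    category_distribution,
    differential_methylation,
    map_probes,
    recurrence,
)
from .occupancy import cluster_bivalent_regions
from .signal import SignalTrack
from .synth import (
    GenomeSpec,
    simulate_annotations,
    simulate_expression,
    simulate_methylomes,
    simulate_peaksets,
    simulate_tracks,
)
from . import io as bio

__all__ = [
    "DEFAULT_PARAMS",
    "simulate_study_files",
    "run_call_domains",
    "run_annotate",
    "run_cluster",
    "run_expression",
    "run_methylation",
    "run_export",
    "run_all",
    "load_hc_regions",
]

DEFAULT_PARAMS = {
    "min_overlap": 1000,
    "min_width": 1000,
    "n_required": None,  # all lines
    "consensus_mode": "union",
    "excluded_chroms": ["chrX", "chrY"],
    "promoter_flank": 1000,
    "kmeans_seed": 1729,
    "kmeans_starts": 50,
    "feature_transform": "log-z",
    "feature_stat": "sum",
    "pseudocount": 0.1,
    "delta_min": 0.25,
    "fdr_max": 0.05,
    "min_types": 5,
}


def _params(cfg: dict) -> dict:
    p = dict(DEFAULT_PARAMS)
    p.update(cfg.get("params", {}))
    return p


def _outdir(cfg: dict) -> Path:
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


# --------------------------------------------------------------------------- #
# simulate
# --------------------------------------------------------------------------- #
def simulate_study_files(outdir, seed: int = 0, scale: Optional[dict] = None) -> dict:
    """Generate a full synthetic study on disk and return its config mapping.

    ``scale`` overrides generator sizes (region counts, n_pairs, n_probes,
    n_tissues, jitter_sd, dropout, effect, noise_sd, ...).
    """
    scale = dict(scale or {})
    outdir = Path(outdir)
    data = outdir / "data"
    data.mkdir(parents=True, exist_ok=True)

    spec_kwargs = {
        k: scale[k]
        for k in (
            "chroms",
            "n_bivalent",
            "n_bivalent_x",
            "n_k4only",
            "n_k27only",
            "n_none_cgi",
            "n_genes",
        )
        if k in scale
    }
    spec = GenomeSpec(seed=seed, **spec_kwargs)
    bundle, truth = simulate_annotations(spec)
    peaksets = simulate_peaksets(
        truth,
        jitter_sd=scale.get("jitter_sd", 0.0),
        dropout=scale.get("dropout", 0.0),
    )
    tracks = simulate_tracks(truth)
    methylome = simulate_methylomes(
        truth,
        n_pairs=scale.get("n_pairs", 20),
        n_types=scale.get("n_types", 8),
        effect=scale.get("effect", 0.4),
        noise_sd=scale.get("noise_sd", 0.05),
        n_probes=scale.get("n_probes", 20_000),
        n_hyper_pos=scale.get("n_hyper_pos", 400),
        n_hyper_neg=scale.get("n_hyper_neg", 120),
        chrom_lengths=spec.chroms,
    )
    expr = simulate_expression(truth, n_tissues=scale.get("n_tissues", 34))

    # --- write inputs in the external dialects the readers consume ---
    peak_paths: Dict[str, Dict[str, str]] = {}
    for mark, by_line in peaksets.items():
        peak_paths[mark] = {}
        for line, ps in by_line.items():
            path = data / f"{line}_{mark}.bed"
            bio.write_peaks(path, ps)
            peak_paths[mark][line] = str(path)
    track_paths = {}
    for factor, track in tracks.items():
        path = data / f"{factor}.bedgraph"
        bio.write_bedgraph(path, track.to_bedgraph_frame())
        track_paths[factor] = str(path)
    bio.write_genes_bed(data / "genes.bed", bundle.genes)
    repeat_rows = [
        (iv.chrom, iv.start, iv.end, cls)
        for cls, iset in sorted(bundle.repeats.items())
        for iv in iset
    ]
    bio.write_bed(data / "repeats.bed", sorted(repeat_rows))
    bio.write_bed(data / "cgis.bed", [(iv.chrom, iv.start, iv.end) for iv in bundle.cgis])
    bio.write_bed(
        data / "enhancers.bed", [(iv.chrom, iv.start, iv.end) for iv in bundle.enhancers]
    )
    bio.write_manifest(data / "manifest.tsv", methylome.manifest)
    bio.write_beta_matrix(data / "beta.tsv", methylome.beta)
    bio.write_sample_sheet(data / "samples.tsv", methylome.samples)
    bio.write_expression(data / "expression.tsv", expr)

    # --- machine-readable planted truth, so tests never re-derive it ---
    truth.regions.to_csv(data / "truth_regions.tsv", sep="\t", index=False)
    truth.genes.to_csv(data / "truth_genes.tsv", sep="\t", index=False)
    hyper_rows = [
        {"tumor_type": t, "cimp": arm, "probe_id": p}
        for (t, arm), probes in sorted(truth.hyper.items())
        for p in sorted(probes)
    ]
    pd.DataFrame(hyper_rows, columns=["tumor_type", "cimp", "probe_id"]).to_csv(
        data / "truth_hyper.tsv", sep="\t", index=False
    )

    cfg = {
        "seed": seed,
        "outdir": str(outdir / "results"),
        "inputs": {
            "peaks": peak_paths,
            "tracks": track_paths,
            "genes": str(data / "genes.bed"),
            "cgis": str(data / "cgis.bed"),
            "repeats": str(data / "repeats.bed"),
            "enhancers": str(data / "enhancers.bed"),
            "manifest": str(data / "manifest.tsv"),
            "beta": str(data / "beta.tsv"),
            "samples": str(data / "samples.tsv"),
            "expression": str(data / "expression.tsv"),
        },
        "params": dict(DEFAULT_PARAMS),
    }
    import yaml

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg


# --------------------------------------------------------------------------- #
# domain calling
# --------------------------------------------------------------------------- #
def _read_peaksets(cfg: dict, mark: str) -> Dict[str, "PeakSet"]:
    paths = cfg["inputs"]["peaks"].get(mark)
    if not paths:
        raise FileNotFoundError(f"no peak files configured for mark {mark}")
    return {line: bio.read_peaks(p, line, mark) for line, p in paths.items()}


def run_call_domains(cfg: dict) -> Dict[str, List[ConsensusRegion]]:
    p = _params(cfg)
    k4 = _read_peaksets(cfg, "H3K4me3")
    k27 = _read_peaksets(cfg, "H3K27me3")
    lists = build_hc_lists(
        k4,
        k27,
        min_overlap=p["min_overlap"],
        min_width=p["min_width"],
        n_required=p["n_required"],
        consensus_mode=p["consensus_mode"],
        excluded_chroms=p["excluded_chroms"],
    )
    out = _outdir(cfg)
    rows = []
    for key in ("bivalent", "K4only", "K27only"):
        for r in lists[key]:
            iv = r.interval
            rows.append(
                {
                    "region_id": r.region_id,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "category": r.category,
                    "n_lines_support": r.n_lines,
                    "supporting_lines": ",".join(sorted(r.supporting_lines)),
                }
            )
    pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable").to_csv(
        out / "hc_regions.tsv", sep="\t", index=False
    )
    merged_rows = [
        {
            "region_id": r.region_id,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "n_lines_support": r.n_lines,
            "supporting_lines": ",".join(sorted(r.supporting_lines)),
        }
        for r in lists["merged_bivalent"]
    ]
    pd.DataFrame(merged_rows).to_csv(out / "merged_bivalent.tsv", sep="\t", index=False)
    return lists


def load_hc_regions(path) -> List[ConsensusRegion]:
    """Rebuild ConsensusRegion objects from a written region table."""
    df = bio.read_region_table(path)
    regions = []
    for r in df.itertuples():
        cluster = getattr(r, "cluster", "")
        regions.append(
            ConsensusRegion(
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
                category=r.category,
                supporting_lines=frozenset(str(r.supporting_lines).split(",")),
                region_id=r.region_id,
                cluster=int(cluster) if str(cluster) not in ("", "nan") else None,
            )
        )
    return regions


# --------------------------------------------------------------------------- #
# annotation
# --------------------------------------------------------------------------- #
def _load_bundle(cfg: dict) -> AnnotationBundle:
    p = _params(cfg)
    return AnnotationBundle(
        genes=bio.read_genes_bed(cfg["inputs"]["genes"]),
        cgis=bio.read_plain_bed(cfg["inputs"]["cgis"]),
        repeats=bio.read_class_bed(cfg["inputs"]["repeats"]),
        enhancers=bio.read_plain_bed(cfg["inputs"]["enhancers"]),
        promoter_flank=p["promoter_flank"],
    )


def run_annotate(
    cfg: dict, lists: Optional[Dict[str, List[ConsensusRegion]]] = None
) -> Tuple[List[AnnotatedRegion], pd.Series, AnnotationBundle]:
    p = _params(cfg)
    out = _outdir(cfg)
    bundle = _load_bundle(cfg)
    if lists is None:
        lists = run_call_domains(cfg)
    regions = lists["bivalent"] + lists["K4only"] + lists["K27only"]
    annotated = annotate_regions(regions, bundle)
    signatures = promoter_signatures(regions, bundle.genes, flank=p["promoter_flank"])
    bio.write_region_table(out / "region_table.tsv", annotated)
    bio.write_browser_track(out / "browser_track.bed", annotated)
    signatures.to_csv(out / "promoter_signatures.tsv", sep="\t", header=True)

    # retroelement frequency profiles per promoter class
    sig_genes = bundle.genes.merge(
        signatures.rename("signature"), left_on="gene_id", right_index=True
    )
    profiles = []
    for cls in ("bivalent", "K4only", "K27only"):
        tss = sig_genes[sig_genes["signature"] == cls]
        if tss.empty:
            continue
        prof = retroelement_profile(tss, bundle.repeats)
        prof["promoter_class"] = cls
        profiles.append(prof.reset_index())
    if profiles:
        pd.concat(profiles).to_csv(out / "retroelement_profiles.tsv", sep="\t", index=False)
    return annotated, signatures, bundle


# --------------------------------------------------------------------------- #
# clustering
# --------------------------------------------------------------------------- #
def run_cluster(
    cfg: dict, lists: Optional[Dict[str, List[ConsensusRegion]]] = None
) -> Tuple[pd.DataFrame, pd.Series]:
    p = _params(cfg)
    out = _outdir(cfg)
    if lists is None:
        lists = run_call_domains(cfg)
    tracks = {
        f: SignalTrack.from_bedgraph_frame(bio.read_bedgraph(path))
        for f, path in cfg["inputs"]["tracks"].items()
    }
    features, clusters = cluster_bivalent_regions(
        lists["bivalent"],
        tracks,
        seed=p["kmeans_seed"],
        n_starts=p["kmeans_starts"],
        transform=p["feature_transform"],
        stat=p["feature_stat"],
    )
    features.to_csv(out / "factor_features.tsv", sep="\t", index_label="region_id")
    clusters.to_csv(out / "bivalent_clusters.tsv", sep="\t", index_label="region_id")
    return features, clusters


def gene_clusters(
    annotated: Sequence[AnnotatedRegion], signatures: pd.Series
) -> pd.Series:
    """Bivalent cluster per bivalent-signature gene (first region by id)."""
    mapping: Dict[str, int] = {}
    for a in sorted(annotated, key=lambda a: a.region.region_id):
        if a.region.category != "bivalent" or a.region.cluster is None:
            continue
        for g in a.gene_ids:
            mapping.setdefault(g, int(a.region.cluster))
    ser = pd.Series(mapping, name="cluster").sort_index()
    biv_genes = signatures.index[signatures == "bivalent"]
    return ser.reindex(ser.index.intersection(biv_genes)).astype(int)


# --------------------------------------------------------------------------- #
# expression
# --------------------------------------------------------------------------- #
def run_expression(
    cfg: dict,
    signatures: pd.Series,
    clusters_by_gene: pd.Series,
) -> Dict[str, pd.DataFrame]:
    p = _params(cfg)
    out = _outdir(cfg)
    expr = bio.read_expression(cfg["inputs"]["expression"])
    summary = class_expression_summary(expr, signatures, pseudocount=p["pseudocount"])
    normalized = normalize_to_k4(expr, signatures, pseudocount=p["pseudocount"])
    medians = cluster_expression_medians(normalized, clusters_by_gene, signatures)
    iqr = iqr_by_gene(normalized, signatures)
    summary.to_csv(out / "expression_class_summary.tsv", sep="\t", index=False)
    medians.to_csv(out / "cluster_expression_medians.tsv", sep="\t", index_label="group")
    iqr.to_csv(out / "expression_iqr.tsv", sep="\t", header=True)
    return {"summary": summary, "normalized": normalized, "medians": medians, "iqr": iqr}


# --------------------------------------------------------------------------- #
# methylation
# --------------------------------------------------------------------------- #
def run_methylation(
    cfg: dict, regions: Sequence[ConsensusRegion]
) -> Dict[str, object]:
    p = _params(cfg)
    out = _outdir(cfg)
    manifest = bio.read_manifest(cfg["inputs"]["manifest"])
    beta = bio.read_beta_matrix(cfg["inputs"]["beta"])
    samples = bio.read_sample_sheet(cfg["inputs"]["samples"])
    probe_cats = map_probes(manifest, regions)
    bio.write_array_annotation(out / "array_annotation.tsv", probe_cats)

    results = differential_methylation(
        beta, samples, delta_min=p["delta_min"], fdr_max=p["fdr_max"]
    )
    dist_rows = []
    hyper_sets: Dict[str, Dict[str, set]] = {"positive": {}, "negative": {}}
    for (ttype, arm), res in sorted(results.items()):
        res[["delta_beta", "t_mod", "p", "q", "call"]].to_csv(
            out / f"dmp_{ttype}_{arm}.tsv", sep="\t", index_label="probe_id"
        )
        hyper_sets[arm][ttype] = set(res.index[res["call"] == "hyper"])
        dist = category_distribution(res, probe_cats, manifest)
        for direction in ("hyper", "hypo"):
            entry = dist[direction]
            if entry is None:
                continue
            row = {
                "tumor_type": ttype,
                "cimp": arm,
                "direction": direction,
                "n_probes": entry["n"],
            }
            row.update(
                {f"frac_{k}": v for k, v in entry["fractions"].items()}
            )
            if "cluster_fractions" in entry:
                row.update(
                    {
                        f"frac_cluster{int(k)}": v
                        for k, v in entry["cluster_fractions"].items()
                    }
                )
            dist_rows.append(row)
    dist_df = pd.DataFrame(dist_rows)
    dist_df.to_csv(out / "category_distributions.tsv", sep="\t", index=False)

    promoter_region = probe_cats["region_id"].where(
        probe_cats["region_id"].notna()
    )
    rec = {}
    for arm, sets in hyper_sets.items():
        if len(sets) >= p["min_types"]:
            rec[arm] = recurrence(sets, min_types=p["min_types"], probe_regions=promoter_region)
            pd.Series(sorted(rec[arm]["probes"]), name="probe_id").to_csv(
                out / f"recurrent_probes_{arm}.tsv", sep="\t", index=False
            )
    return {
        "probe_categories": probe_cats,
        "results": results,
        "distributions": dist_df,
        "recurrence": rec,
    }


# --------------------------------------------------------------------------- #
# export + run-all
# --------------------------------------------------------------------------- #
def run_export(cfg: dict, annotated: Sequence[AnnotatedRegion], probe_cats: pd.DataFrame) -> None:
    out = _outdir(cfg)
    bio.write_region_table(out / "region_table.tsv", annotated)
    bio.write_browser_track(out / "browser_track.bed", annotated)
    bio.write_array_annotation(out / "array_annotation.tsv", probe_cats)


def run_all(cfg: dict) -> Dict[str, object]:
    """Execute the full pipeline and write a deterministic run log."""
    p = _params(cfg)
    out = _outdir(cfg)
    lists = run_call_domains(cfg)
    features, clusters = run_cluster(cfg, lists)
    annotated, signatures, bundle = run_annotate(cfg, lists)
    clusters_gene = gene_clusters(annotated, signatures)
    expression = run_expression(cfg, signatures, clusters_gene)
    regions = lists["bivalent"] + lists["K4only"] + lists["K27only"]
    methylation = run_methylation(cfg, regions)

    log = {
        "package_version": __version__,
        "seed": cfg.get("seed"),
        "params": p,
        "input_checksums": {
            name: bio.file_checksum(path)
            for name, path in sorted(_flatten_inputs(cfg["inputs"]))
        },
        "n_regions": {
            "bivalent": len(lists["bivalent"]),
            "K4only": len(lists["K4only"]),
            "K27only": len(lists["K27only"]),
            "merged_bivalent": len(lists["merged_bivalent"]),
        },
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        for key, val in sorted(log.items()):
            fh.write(f"{key}={val}\n")
    return {
        "lists": lists,
        "annotated": annotated,
        "signatures": signatures,
        "features": features,
        "clusters": clusters,
        "expression": expression,
        "methylation": methylation,
    }


def _flatten_inputs(inputs: dict, prefix: str = "") -> List[Tuple[str, str]]:
    out = []
    for key, val in inputs.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            out.extend(_flatten_inputs(val, prefix=f"{name}."))
        else:
            out.append((name, val))
    return out
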