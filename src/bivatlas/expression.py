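"""Expression integration for promoter chromatin-signature gene classes.

Expression is summarized on log2(RPKM + pseudocount); for cross-tissue
comparisons the values are normalized per tissue to the median of
H3K4me3-only-promoter genes, which is globally stable across tissues, so a
value of 0 means "as expressed as a typical constitutively active gene".
Genes with mixed promoter signatures are excluded from all summaries.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "class_expression_summary",
    "normalize_to_k4",
    "cluster_expression_medians",
    "iqr_by_gene",
]

EXPRESSION_CLASSES = ("K4only", "bivalent", "K27only")
DEFAULT_PSEUDOCOUNT = 0.1


def _check_expr(expr: pd.DataFrame) -> None:
    if (expr.to_numpy() < 0).any():
        raise ValueError("RPKM matrix contains negative values")


def _classed_genes(expr: pd.DataFrame, signatures: pd.Series, cls: str) -> pd.Index:
    genes = signatures.index[signatures == cls]
    return expr.index.intersection(genes)


def class_expression_summary(
    expr: pd.DataFrame,
    signatures: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Median and quartiles of log2(RPKM+eps) per signature class per tissue.

    Mixed-signature genes are dropped.  Classes with no genes are absent from
    the output (not reported as zero).
    """
    _check_expr(expr)
    log = np.log2(expr + pseudocount)
    rows = []
    for cls in EXPRESSION_CLASSES:
        genes = _classed_genes(expr, signatures, cls)
        if len(genes) == 0:
            continue
        sub = log.loc[genes]
        for tissue in expr.columns:
            v = sub[tissue]
            rows.append(
                {
                    "class": cls,
                    "tissue": tissue,
                    "n_genes": len(genes),
                    "q1": float(v.quantile(0.25)),
                    "median": float(v.median()),
                    "q3": float(v.quantile(0.75)),
                }
            )
    return pd.DataFrame(rows)


def normalize_to_k4(
    expr: pd.DataFrame,
    signatures: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """log2 RPKM centered, per tissue, on the K4only-gene median.

    value(g, t) = log2(RPKM(g,t)+eps) - median_{g' in K4only} log2(RPKM(g',t)+eps)
    """
    _check_expr(expr)
    k4 = _classed_genes(expr, signatures, "K4only")
    if len(k4) == 0:
        raise ValueError("no H3K4me3-only genes present; cannot normalize")
    log = np.log2(expr + pseudocount)
    ref = log.loc[k4].median(axis=0)
    return log.sub(ref, axis=1)


def cluster_expression_medians(
    normalized: pd.DataFrame,
    clusters: pd.Series,
    signatures: pd.Series,
) -> pd.DataFrame:
    """Per-tissue medians of normalized expression for bivalent genes.

    Rows: 'all' (every bivalent gene) and each present cluster (1..3); empty
    clusters are simply absent.
    """
    biv = _classed_genes(normalized, signatures, "bivalent")
    out: Dict[str, pd.Series] = {}
    if len(biv):
        out["all"] = normalized.loc[biv].median(axis=0)
    for c in (1, 2, 3):
        genes = normalized.index.intersection(
            clusters.index[clusters == c]
        ).intersection(biv)
        if len(genes):
            out[str(c)] = normalized.loc[genes].median(axis=0)
    return pd.DataFrame(out).T


def iqr_by_gene(
    normalized: pd.DataFrame, signatures: Optional[pd.Series] = None
) -> pd.Series:
    """Per-gene interquartile range across tissues (type-7 linear quantiles)."""
    if normalized.shape[1] < 4:
        raise ValueError("need >= 4 tissues for a meaningful IQR")
    x = normalized.to_numpy(dtype=float)
    q1 = np.percentile(x, 25, axis=1)  # numpy default: linear interpolation
    q3 = np.percentile(x, 75, axis=1)
    iqr = pd.Series(q3 - q1, index=normalized.index, name="iqr")
    if signatures is not None:
        keep = signatures.reindex(normalized.index).isin(EXPRESSION_CLASSES)
        iqr = iqr[keep.to_numpy()]
    return iqr
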