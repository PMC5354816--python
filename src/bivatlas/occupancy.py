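"""Mark/factor occupancy at HC regions and K-means clustering of bivalent promoters.

Histone marks are assigned to a region only when an overlapping peak is
present in both reference lines (H1 and H9).  Transcription-factor occupancy
keeps peaks at FDR < 0.05.  Bivalent regions are partitioned into three
clusters by K-means on the summed RPM of four factors (EZH2, PolII, TAF1,
TCF12) over the region +/- 1 kbp, and the clusters are relabeled
semantically: cluster 1 = PolII/TAF1-high, cluster 2 = EZH2-high among the
remainder, cluster 3 = the rest.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .domains import ConsensusRegion
from .intervals import GenomicInterval, PeakSet
from .signal import SignalTrack

__all__ = [
    "assign_marks_two_lines",
    "tf_occupancy",
    "chi_squared_2x2",
    "signal_matrix",
    "extract_features",
    "kmeans_three",
    "label_clusters",
    "cluster_bivalent_regions",
    "FACTORS",
]

FACTORS = ("EZH2", "PolII", "TAF1", "TCF12")


def assign_marks_two_lines(
    region: ConsensusRegion, peaks_line_a: PeakSet, peaks_line_b: PeakSet
) -> bool:
    """True iff the region overlaps >= 1 peak of the mark in *both* lines."""
    if peaks_line_a.mark != peaks_line_b.mark:
        raise ValueError("peak sets carry different marks")
    iv = region.interval
    return peaks_line_a.interval_set.overlaps_any(iv) and peaks_line_b.interval_set.overlaps_any(iv)


def tf_occupancy(
    regions_by_category: Dict[str, Sequence[ConsensusRegion]],
    tf_peaks: PeakSet,
    fdr_max: float = 0.05,
) -> pd.Series:
    """Fraction of regions per category overlapping >= 1 FDR-retained peak."""
    retained = tf_peaks.filter_fdr(fdr_max)
    iset = retained.interval_set
    out = {}
    for cat, regions in regions_by_category.items():
        regions = list(regions)
        if not regions:
            out[cat] = np.nan
            continue
        hits = sum(iset.overlaps_any(r.interval) for r in regions)
        out[cat] = hits / len(regions)
    return pd.Series(out, name=tf_peaks.mark)


def chi_squared_2x2(
    occupied_a: int, total_a: int, occupied_b: int, total_b: int
) -> Tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2 table."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= occupied_a <= total_a and 0 <= occupied_b <= total_b):
        raise ValueError("counts must be within totals")
    table = np.array(
        [
            [occupied_a, total_a - occupied_a],
            [occupied_b, total_b - occupied_b],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined: an expected cell is zero")
    res = stats.chi2_contingency(table, correction=False)
    return float(res[0]), float(res[1])


def signal_matrix(
    regions: Sequence[ConsensusRegion],
    track: SignalTrack,
    half_window: int,
    n_bins: int,
    anchor: str = "region-center",
) -> Tuple[pd.DataFrame, pd.Series]:
    """Regions x bins matrix of mean RPM, anchored on region centers.

    Returns (matrix, column-mean profile); rows follow the input region order.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if anchor != "region-center":
        raise ValueError(f"unknown anchor {anchor!r}")
    bin_width = 2 * half_window / n_bins
    if bin_width < 1:
        raise ValueError("half_window must give bins of >= 1 bp")
    mat = np.zeros((len(regions), n_bins))
    ids = []
    for i, r in enumerate(regions):
        iv = r.interval
        center = (iv.start + iv.end) // 2
        edges = np.round(center - half_window + bin_width * np.arange(n_bins + 1)).astype(int)
        for k in range(n_bins):
            lo, hi = max(0, int(edges[k])), int(edges[k + 1])
            if hi > lo:
                mat[i, k] = track.rpm_mean(iv.chrom, lo, hi)
        ids.append(r.region_id or f"region{i}")
    offsets = (np.arange(n_bins) + 0.5) * bin_width - half_window
    df = pd.DataFrame(mat, index=ids, columns=np.round(offsets).astype(int))
    return df, df.mean(axis=0)


def extract_features(
    regions: Sequence[ConsensusRegion],
    tracks: Dict[str, SignalTrack],
    flank: int = 1000,
    stat: str = "sum",
) -> pd.DataFrame:
    """Per-region RPM of each factor over region +/- flank.

    ``stat``: 'sum' (global summed RPM, default) or 'mean'.
    """
    missing = [f for f in FACTORS if f not in tracks]
    if missing:
        raise ValueError(f"missing factor tracks: {missing}")
    rows = []
    ids = []
    for i, r in enumerate(regions):
        iv = r.interval
        lo, hi = max(0, iv.start - flank), iv.end + flank
        vals = []
        for f in FACTORS:
            s = tracks[f].rpm_sum(iv.chrom, lo, hi)
            vals.append(s / (hi - lo) if stat == "mean" else s)
        rows.append(vals)
        ids.append(r.region_id or f"region{i}")
    df = pd.DataFrame(rows, index=ids, columns=list(FACTORS))
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite feature values")
    return df


def _transform_features(features: pd.DataFrame, transform: str) -> np.ndarray:
    x = features.to_numpy(dtype=float)
    if transform == "none":
        return x
    if transform != "log-z":
        raise ValueError(f"unknown transform {transform!r}")
    x = np.log2(x + 1.0)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant factor carries no information
    return (x - mu) / sd


def kmeans_three(
    features: pd.DataFrame,
    k: int = 3,
    seed: int = 1729,
    n_starts: int = 50,
    transform: str = "log-z",
) -> pd.Series:
    """K-means partition of the factor features into ``k`` clusters.

    Features are log2(x+1)-transformed and z-scored per factor (raw RPM would
    let the strongest factor dominate the Euclidean metric).  Rows are put in
    a canonical (lexicographic) order before fitting so the partition does
    not depend on input order; labels are then assigned to the original rows
    by nearest centroid.  Returns raw (unsemantic) labels 0..k-1 indexed like
    ``features``.
    """
    x = _transform_features(features, transform)
    if len(np.unique(x, axis=0)) < k:
        raise ValueError(f"need >= {k} distinct feature vectors")
    canon = np.lexsort(x.T[::-1])
    km = KMeans(
        n_clusters=k,
        n_init=n_starts,
        random_state=seed,
        tol=1e-6,
        algorithm="lloyd",
    ).fit(x[canon])
    labels = km.predict(x)
    return pd.Series(labels, index=features.index, name="raw_cluster")


def label_clusters(
    assignments: pd.Series, features: pd.DataFrame
) -> pd.Series:
    """Relabel raw K-means clusters semantically as 1, 2, 3.

    1 = highest mean PolII+TAF1; 2 = highest mean EZH2 among the remaining
    two; 3 = the other.  Ties broken by cluster size descending, then by raw
    label for full determinism.
    """
    raw_labels = sorted(assignments.unique())
    if len(raw_labels) != 3:
        raise ValueError("semantic labeling requires exactly 3 clusters")
    sizes = assignments.value_counts()

    def keyed(metric: pd.Series):
        # sort candidates by (metric desc, size desc, raw label asc)
        return sorted(
            metric.index, key=lambda c: (-metric[c], -sizes[c], c)
        )

    polta = (features["PolII"] + features["TAF1"]).groupby(assignments).mean()
    c1 = keyed(polta)[0]
    remaining = [c for c in raw_labels if c != c1]
    ezh2 = features["EZH2"].groupby(assignments).mean().loc[remaining]
    c2 = keyed(ezh2)[0]
    c3 = next(c for c in remaining if c != c2)
    mapping = {c1: 1, c2: 2, c3: 3}
    return assignments.map(mapping).rename("cluster")


def cluster_bivalent_regions(
    regions: Sequence[ConsensusRegion],
    tracks: Dict[str, SignalTrack],
    seed: int = 1729,
    n_starts: int = 50,
    flank: int = 1000,
    transform: str = "log-z",
    stat: str = "sum",
) -> Tuple[pd.DataFrame, pd.Series]:
    """Extract four-factor features, cluster, label semantically, attach labels.

    Mutates ``regions`` in place by setting ``cluster``; also returns
    (features, cluster Series).
    """
    features = extract_features(regions, tracks, flank=flank, stat=stat)
    raw = kmeans_three(features, seed=seed, n_starts=n_starts, transform=transform)
    clusters = label_clusters(raw, features)
    for r in regions:
        r.cluster = int(clusters.loc[r.region_id])
    return features, clusters
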