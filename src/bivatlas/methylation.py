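"""Methylation-array integration: probe mapping, beta bands, differential calls.

Probes are mapped to the chromatin-state region containing their position
(regions are pairwise disjoint, so each probe gets exactly one category).
Differential methylation between tumor and matched normal samples is an
unpaired two-group comparison on beta values with an empirical-Bayes
moderated t-statistic (limma-style): per-probe residual variances are shrunk
toward a prior (d0, s0^2) estimated by method of moments on the log sample
variances, and the moderated t is referred to a t distribution with d0 + d
degrees of freedom.  Probes are called hyper-/hypomethylated when the
BH-adjusted p-value is below alpha and |delta beta| exceeds the effect
threshold (0.25).  CIMP-positive and CIMP-negative tumors are analyzed
separately against their own matched normals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .domains import ConsensusRegion

__all__ = [
    "map_probes",
    "beta_categories",
    "moderated_t_test",
    "bh_fdr",
    "call_dmps",
    "differential_methylation",
    "stratify_cimp",
    "category_distribution",
    "recurrence",
    "trigamma_inverse",
    "BETA_BANDS",
    "CHROMATIN_CATEGORIES",
]

CHROMATIN_CATEGORIES = ("none", "bivalent", "K4only", "K27only")
BETA_BANDS = ("beta<0.1", "0.1<=beta<0.3", "0.3<=beta<=0.7", "beta>0.7")

DELTA_MIN_DEFAULT = 0.25
FDR_MAX_DEFAULT = 0.05


# --------------------------------------------------------------------------- #
# probe mapping and beta bands
# --------------------------------------------------------------------------- #
def map_probes(
    manifest: pd.DataFrame, regions: Sequence[ConsensusRegion]
) -> pd.DataFrame:
    """Chromatin category (+ region id, cluster) for every manifest probe.

    ``manifest`` needs columns probe_id, chrom, position (0-based).  A probe
    belongs to the region whose half-open interval contains its position;
    'none' otherwise.  Regions must be pairwise disjoint.
    """
    by_chrom: Dict[str, List[ConsensusRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    arrs: Dict[str, Tuple[np.ndarray, np.ndarray, List[ConsensusRegion]]] = {}
    for chrom, regs in by_chrom.items():
        regs.sort(key=lambda r: r.interval.start)
        starts = np.array([r.interval.start for r in regs])
        ends = np.array([r.interval.end for r in regs])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"regions overlap on {chrom}; mapping is ambiguous")
        arrs[chrom] = (starts, ends, regs)

    cats, rids, clusters = [], [], []
    for row in manifest.itertuples():
        chrom, pos = row.chrom, int(row.position)
        hit = None
        if chrom in arrs:
            starts, ends, regs = arrs[chrom]
            i = int(np.searchsorted(starts, pos, side="right") - 1)
            if i >= 0 and pos < ends[i]:
                hit = regs[i]
        if hit is None:
            cats.append("none")
            rids.append(None)
            clusters.append(np.nan)
        else:
            cats.append(hit.category)
            rids.append(hit.region_id or None)
            clusters.append(hit.cluster if hit.cluster is not None else np.nan)
    return pd.DataFrame(
        {
            "probe_id": manifest["probe_id"].to_numpy(),
            "category": cats,
            "region_id": rids,
            "cluster": clusters,
        }
    ).set_index("probe_id")


def beta_categories(
    beta: pd.Series,
    thresholds: Tuple[float, float, float] = (0.1, 0.3, 0.7),
) -> pd.Series:
    """Band each probe's beta value: <0.1 / [0.1,0.3) / [0.3,0.7] / >0.7.

    Missing values stay missing; the bands partition all non-missing probes.
    """
    low, unmeth, meth = thresholds
    v = beta.to_numpy(dtype=float)
    if np.nanmin(v) < 0 or np.nanmax(v) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    out = np.full(len(v), None, dtype=object)
    ok = ~np.isnan(v)
    out[ok & (v < low)] = BETA_BANDS[0]
    out[ok & (v >= low) & (v < unmeth)] = BETA_BANDS[1]
    out[ok & (v >= unmeth) & (v <= meth)] = BETA_BANDS[2]
    out[ok & (v > meth)] = BETA_BANDS[3]
    return pd.Series(out, index=beta.index, name="band")


def band_counts_by_category(
    beta: pd.Series, probe_categories: pd.Series
) -> pd.DataFrame:
    """Probe counts per beta band per chromatin category."""
    bands = beta_categories(beta)
    df = pd.DataFrame({"band": bands, "category": probe_categories.reindex(bands.index)})
    df = df.dropna(subset=["band"])
    table = df.groupby(["category", "band"]).size().unstack(fill_value=0)
    return table.reindex(columns=list(BETA_BANDS), fill_value=0)


# --------------------------------------------------------------------------- #
# moderated t
# --------------------------------------------------------------------------- #
def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> Tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from sample variances.

    Model: s2_g ~ s0^2 * F(df_g, d0).  On z = log s2 the first two moments
    involve digamma/trigamma functions; d0 is recovered by inverting the
    trigamma function.  Returns (d0, s0^2); d0 = inf when the observed
    spread of log variances does not exceed its sampling expectation, in
    which case s0^2 is the arithmetic mean of the sample variances.
    """
    ok = (s2 > 1e-300) & (df > 0)
    if ok.sum() < 2:
        raise RuntimeError("too few probes with positive variance to fit the prior")
    z = np.log(s2[ok])
    half_df = df[ok] / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, half_df).mean()
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.mean(s2[ok]))
    if not np.isfinite(s0_sq) or s0_sq <= 0:
        raise RuntimeError("variance prior estimation failed")
    return d0, s0_sq


def moderated_t_test(
    beta: pd.DataFrame,
    labels: Sequence[str],
    d0: Optional[float] = None,
    s0_sq: Optional[float] = None,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-probe two-group (tumor vs normal) moderated t on beta values.

    ``beta`` is probes x samples; ``labels`` gives 'tumor'/'normal' per
    column.  Missing values are allowed: a probe is tested only when it has
    at least ``min_per_group`` non-missing values in each group (untested
    probes get NaN statistics and tested=False).

    ``d0``/``s0_sq`` override the empirical-Bayes prior (d0=0 reproduces the
    ordinary two-sample t).  Returns a DataFrame with columns delta_beta,
    t_mod, p, df_total, tested and attrs 'd0', 's0_sq'.
    """
    labels = np.asarray(labels)
    if len(labels) != beta.shape[1]:
        raise ValueError("labels length must equal the number of samples")
    t_idx = labels == "tumor"
    n_idx = labels == "normal"
    if t_idx.sum() < min_per_group or n_idx.sum() < min_per_group:
        raise ValueError("need >= 2 samples per group")
    x = beta.to_numpy(dtype=float)
    xt, xn = x[:, t_idx], x[:, n_idx]
    n1 = np.sum(~np.isnan(xt), axis=1)
    n2 = np.sum(~np.isnan(xn), axis=1)
    tested = (n1 >= min_per_group) & (n2 >= min_per_group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        m1 = np.nanmean(xt, axis=1)
        m2 = np.nanmean(xn, axis=1)
        v1 = np.nanvar(xt, axis=1, ddof=1)
        v2 = np.nanvar(xn, axis=1, ddof=1)
    delta = m1 - m2
    resid_df = (n1 + n2 - 2).astype(float)
    s2 = np.where(
        resid_df > 0,
        ((n1 - 1) * np.nan_to_num(v1) + (n2 - 1) * np.nan_to_num(v2))
        / np.maximum(resid_df, 1.0),
        np.nan,
    )
    if np.all(resid_df[tested] <= 0):
        raise ValueError("zero residual degrees of freedom")

    if d0 is None or s0_sq is None:
        try:
            d0_fit, s0_fit = _fit_variance_prior(s2[tested], resid_df[tested])
        except RuntimeError as exc:
            warnings.warn(
                f"variance prior estimation failed ({exc}); "
                "falling back to the ordinary t-test",
                RuntimeWarning,
            )
            d0_fit, s0_fit = 0.0, 1.0
        if d0 is None:
            d0 = d0_fit
        if s0_sq is None:
            s0_sq = s0_fit

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_mod = s2
    else:
        s2_mod = (d0 * s0_sq + resid_df * s2) / (d0 + resid_df)
    se = np.sqrt(s2_mod * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = delta / se
    df_total = d0 + resid_df
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t_mod)),
        2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    out = pd.DataFrame(
        {
            "delta_beta": delta,
            "t_mod": np.where(tested, t_mod, np.nan),
            "p": np.where(tested, p, np.nan),
            "df_total": np.where(tested, df_total, np.nan),
            "s2": s2,
            "tested": tested,
        },
        index=beta.index,
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0_sq"] = float(s0_sq)
    return out


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone), NaN-safe."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_dmps(
    results: pd.DataFrame,
    delta_min: float = DELTA_MIN_DEFAULT,
    fdr_max: float = FDR_MAX_DEFAULT,
) -> pd.DataFrame:
    """Add q-values and hyper/hypo/none calls to a moderated-t result table.

    hyper: delta_beta > delta_min and q < fdr_max;
    hypo:  delta_beta < -delta_min and q < fdr_max (the effect threshold is
    read symmetrically).
    """
    out = results.copy()
    out["q"] = bh_fdr(out["p"].to_numpy())
    call = np.full(len(out), "none", dtype=object)
    sig = out["q"].to_numpy() < fdr_max
    call[sig & (out["delta_beta"].to_numpy() > delta_min)] = "hyper"
    call[sig & (out["delta_beta"].to_numpy() < -delta_min)] = "hypo"
    call[~out["tested"].to_numpy()] = "none"
    out["call"] = call
    out.attrs.update(results.attrs)
    return out


# --------------------------------------------------------------------------- #
# CIMP stratification and distributions
# --------------------------------------------------------------------------- #
def stratify_cimp(samples: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Split a sample sheet into CIMP arms (tumors + their matched normals).

    ``samples`` needs columns sample_id, status ('tumor'/'normal'), pair_id,
    cimp ('positive'/'negative'/'NA').  Tumors with CIMP 'NA' are excluded.
    Returns dict arm -> sample subset; an arm with no tumors is absent.
    """
    tumors = samples[samples["status"] == "tumor"]
    normals = samples[samples["status"] == "normal"]
    out: Dict[str, pd.DataFrame] = {}
    for arm in ("positive", "negative"):
        arm_tumors = tumors[tumors["cimp"] == arm]
        if arm_tumors.empty:
            continue
        arm_normals = normals[normals["pair_id"].isin(arm_tumors["pair_id"])]
        out[arm] = pd.concat([arm_tumors, arm_normals], ignore_index=True)
    return out


def differential_methylation(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    delta_min: float = DELTA_MIN_DEFAULT,
    fdr_max: float = FDR_MAX_DEFAULT,
) -> Dict[Tuple[str, str], pd.DataFrame]:
    """Per (tumor type, CIMP arm) differential methylation vs matched normals."""
    results: Dict[Tuple[str, str], pd.DataFrame] = {}
    for ttype, sub in samples.groupby("tumor_type"):
        for arm, arm_samples in stratify_cimp(sub).items():
            cols = [s for s in arm_samples["sample_id"] if s in beta.columns]
            arm_samples = arm_samples[arm_samples["sample_id"].isin(cols)]
            labels = (
                arm_samples.set_index("sample_id").loc[cols, "status"].to_numpy()
            )
            if (labels == "tumor").sum() < 2 or (labels == "normal").sum() < 2:
                continue  # arm too small to analyze; reported as absent
            res = moderated_t_test(beta[cols], labels)
            results[(str(ttype), arm)] = call_dmps(res, delta_min, fdr_max)
    return results


def category_distribution(
    calls: pd.DataFrame,
    probe_categories: pd.DataFrame,
    manifest: Optional[pd.DataFrame] = None,
) -> Dict[str, object]:
    """Distributions of hyper/hypo probes over chromatin categories.

    ``probe_categories`` is the map_probes output (category, cluster).  For
    each call direction present, reports the fraction per category (summing
    to 1), the cluster 1/2/3 split within bivalent probes, and — when a
    manifest with a ``feature`` column is supplied — the genomic-feature
    split.  Also reports the reference distribution over all array probes.
    Directions with zero calls are reported as None (absent), not as zeros.
    """
    cat = probe_categories["category"].reindex(calls.index)
    ref = (
        cat.value_counts(normalize=True)
        .reindex(list(CHROMATIN_CATEGORIES), fill_value=0.0)
    )
    out: Dict[str, object] = {"reference": ref}
    for direction in ("hyper", "hypo"):
        probes = calls.index[calls["call"] == direction]
        if len(probes) == 0:
            out[direction] = None
            continue
        entry: Dict[str, object] = {
            "fractions": cat.loc[probes]
            .value_counts(normalize=True)
            .reindex(list(CHROMATIN_CATEGORIES), fill_value=0.0),
            "n": int(len(probes)),
        }
        biv = probes[cat.loc[probes] == "bivalent"]
        if len(biv):
            entry["cluster_fractions"] = (
                probe_categories["cluster"]
                .reindex(biv)
                .value_counts(normalize=True)
                .reindex([1.0, 2.0, 3.0], fill_value=0.0)
            )
        if manifest is not None and "feature" in manifest.columns:
            feat = manifest.set_index("probe_id")["feature"].reindex(probes)
            entry["feature_fractions"] = feat.value_counts(normalize=True)
        out[direction] = entry
    return out


def recurrence(
    hyper_sets: Mapping[str, Set[str]],
    min_types: int = 5,
    probe_regions: Optional[pd.Series] = None,
) -> Dict[str, object]:
    """Probes hypermethylated in >= ``min_types`` of the supplied analyses.

    ``hyper_sets`` maps tumor type -> set of hyper probe ids (one CIMP arm at
    a time).  When ``probe_regions`` (probe id -> promoter region id) is
    given, the covered promoter regions are reported too.
    """
    if len(hyper_sets) < min_types:
        raise ValueError("fewer analyses supplied than min_types")
    counts: Dict[str, int] = {}
    for probes in hyper_sets.values():
        for p in probes:
            counts[p] = counts.get(p, 0) + 1
    recurrent = {p for p, c in counts.items() if c >= min_types}
    out: Dict[str, object] = {
        "probes": recurrent,
        "n_probes": len(recurrent),
        "counts": counts,
    }
    if probe_regions is not None:
        regions = set(probe_regions.reindex(sorted(recurrent)).dropna().unique())
        out["regions"] = regions
        out["n_regions"] = len(regions)
    return out
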