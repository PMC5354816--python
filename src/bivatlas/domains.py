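"""Bivalent-domain calling and multi-line consensus.

Strategy: per cell line, a bivalent domain is every maximal piece where an
H3K4me3 peak and an H3K27me3 peak overlap for at least 1 kbp.  Per-line
domains are union-merged across lines into consensus regions that record
which lines support them; high-confidence (HC) regions are those supported
by every line.  H3K4me3-only and H3K27me3-only HC lists are the cross-line
intersection of the single mark's peaks (>= 1 kbp pieces) after discarding
any region that overlaps a bivalent domain of any line.  Sex chromosomes
are excluded because hESC lines are of mixed embryo sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet, PeakSet

__all__ = [
    "BivalentDomain",
    "ConsensusRegion",
    "call_bivalent_per_line",
    "merge_across_lines",
    "select_high_confidence",
    "call_exclusive_regions",
    "exclude_chromosomes",
    "build_hc_lists",
    "DEFAULT_EXCLUDED_CHROMS",
]

DEFAULT_EXCLUDED_CHROMS = frozenset({"chrX", "chrY"})

CATEGORY_BIVALENT = "bivalent"
CATEGORY_K4 = "K4only"
CATEGORY_K27 = "K27only"


@dataclass(frozen=True)
class BivalentDomain:
    """One per-line overlap piece of an H3K4me3 and an H3K27me3 peak."""

    interval: GenomicInterval
    cell_line: str
    source_k4: GenomicInterval
    source_k27: GenomicInterval


@dataclass
class ConsensusRegion:
    """A merged cross-line region with category and per-line support."""

    interval: GenomicInterval
    category: str
    supporting_lines: FrozenSet[str]
    region_id: str = ""
    cluster: Optional[int] = None

    @property
    def n_lines(self) -> int:
        return len(self.supporting_lines)


def _containing_interval(arr: np.ndarray, chrom: str, piece: np.ndarray) -> GenomicInterval:
    """Normalized source interval containing the (start, end) piece."""
    idx = int(np.searchsorted(arr[:, 0], piece[0], side="right") - 1)
    return GenomicInterval(chrom, int(arr[idx, 0]), int(arr[idx, 1]))


def call_bivalent_per_line(
    k4: PeakSet, k27: PeakSet, min_overlap: int = 1000
) -> List[BivalentDomain]:
    """Per-line bivalent domains: K4 ∩ K27 pieces of width >= ``min_overlap``."""
    if k4.cell_line != k27.cell_line:
        raise ValueError(
            f"peak sets are from different cell lines: {k4.cell_line!r} vs {k27.cell_line!r}"
        )
    a = k4.interval_set
    b = k27.interval_set
    pieces = a.intersect(b, min_width=min_overlap)
    domains: List[BivalentDomain] = []
    for chrom in pieces.chroms:
        arr4 = a.chrom_array(chrom)
        arr27 = b.chrom_array(chrom)
        for piece in pieces.chrom_array(chrom):
            iv = GenomicInterval(chrom, int(piece[0]), int(piece[1]))
            domains.append(
                BivalentDomain(
                    interval=iv,
                    cell_line=k4.cell_line,
                    source_k4=_containing_interval(arr4, chrom, piece),
                    source_k27=_containing_interval(arr27, chrom, piece),
                )
            )
    return domains


def merge_across_lines(
    domains_by_line: Dict[str, Sequence[BivalentDomain]]
) -> List[ConsensusRegion]:
    """Union-merge per-line domains; support = lines with >= 1 bp overlap."""
    if not domains_by_line:
        return []
    per_line_sets = {
        line: IntervalSet(d.interval for d in doms).normalize()
        for line, doms in domains_by_line.items()
    }
    merged = IntervalSet.empty()
    for iset in per_line_sets.values():
        merged = merged.union(iset)
    regions: List[ConsensusRegion] = []
    for iv in merged:
        lines = frozenset(
            line for line, iset in per_line_sets.items() if iset.overlaps_any(iv)
        )
        regions.append(
            ConsensusRegion(interval=iv, category=CATEGORY_BIVALENT, supporting_lines=lines)
        )
    return regions


def select_high_confidence(
    regions: Iterable[ConsensusRegion], n_required: int
) -> List[ConsensusRegion]:
    """Keep regions supported by at least ``n_required`` lines."""
    return [r for r in regions if r.n_lines >= n_required]


def _support_runs(arrays: Sequence[np.ndarray], n_required: int) -> np.ndarray:
    """Maximal runs of bases covered by >= n_required of the given arrays.

    Event sweep: +1 at starts, -1 at ends, cumulative sum between breakpoints.
    """
    starts = np.concatenate([a[:, 0] for a in arrays if len(a)] or [np.empty(0, int)])
    ends = np.concatenate([a[:, 1] for a in arrays if len(a)] or [np.empty(0, int)])
    if not len(starts):
        return np.empty((0, 2), dtype=np.int64)
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones(len(starts), int), -np.ones(len(ends), int)])
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    upos, idx = np.unique(pos, return_index=True)
    depth = np.add.reduceat(delta, idx).cumsum()
    above = depth >= n_required
    out: List[List[int]] = []
    run_start = None
    for k in range(len(upos)):
        if above[k] and run_start is None:
            run_start = int(upos[k])
        elif not above[k] and run_start is not None:
            out.append([run_start, int(upos[k])])
            run_start = None
    # coverage always returns to zero at the last breakpoint, closing any run
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def consensus_intersection(
    sets: Sequence[IntervalSet], n_required: Optional[int] = None, min_width: int = 1
) -> IntervalSet:
    """Bases covered in >= ``n_required`` sets (default: all), runs >= min_width."""
    if n_required is None:
        n_required = len(sets)
    norm = [s.normalize() for s in sets]
    chroms = set().union(*(set(s.chroms) for s in norm)) if norm else set()
    data: Dict[str, np.ndarray] = {}
    for chrom in chroms:
        runs = _support_runs([s.chrom_array(chrom) for s in norm], n_required)
        if len(runs):
            keep = (runs[:, 1] - runs[:, 0]) >= min_width
            if keep.any():
                data[chrom] = runs[keep]
    return IntervalSet.from_arrays(data)


def call_exclusive_regions(
    mark_peaksets: Dict[str, PeakSet],
    all_bivalent: Dict[str, Sequence[BivalentDomain]],
    min_width: int = 1000,
    n_required: Optional[int] = None,
) -> List[ConsensusRegion]:
    """Single-mark HC regions: cross-line consensus minus anything bivalent.

    A candidate region overlapping (>= 1 bp) a bivalent domain of *any* line is
    discarded entirely (not trimmed).
    """
    marks = {ps.mark for ps in mark_peaksets.values()}
    if len(marks) != 1:
        raise ValueError(f"peak sets carry different marks: {sorted(marks)}")
    mark = marks.pop()
    category = CATEGORY_K4 if "K4" in mark else CATEGORY_K27
    if n_required is None:
        n_required = len(mark_peaksets)
    consensus = consensus_intersection(
        [ps.interval_set for ps in mark_peaksets.values()],
        n_required=n_required,
        min_width=min_width,
    )
    bivalent_any = IntervalSet(
        d.interval for doms in all_bivalent.values() for d in doms
    ).normalize()
    lines = frozenset(mark_peaksets)
    out: List[ConsensusRegion] = []
    for iv in consensus:
        if bivalent_any.overlaps_any(iv):
            continue
        out.append(ConsensusRegion(interval=iv, category=category, supporting_lines=lines))
    return out


def exclude_chromosomes(
    regions: Iterable[ConsensusRegion],
    excluded: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> List[ConsensusRegion]:
    excl = set(excluded)
    return [r for r in regions if r.interval.chrom not in excl]


def _assign_region_ids(regions: List[ConsensusRegion], prefix: str) -> None:
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    for i, r in enumerate(regions, start=1):
        r.region_id = f"{prefix}{i:05d}"


def build_hc_lists(
    k4_by_line: Dict[str, PeakSet],
    k27_by_line: Dict[str, PeakSet],
    min_overlap: int = 1000,
    min_width: int = 1000,
    n_required: Optional[int] = None,
    consensus_mode: str = "union",
    excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> Dict[str, List[ConsensusRegion]]:
    """Run the full domain-calling strategy.

    Returns a dict with keys ``merged_bivalent`` (all support levels),
    ``bivalent``, ``K4only``, ``K27only`` (the three HC lists, pairwise
    disjoint) and ``domains_by_line``.

    ``consensus_mode``: 'union' (default) merges per-line domains and counts
    per-line support on the merged region; 'intersection' instead takes the
    all-lines per-base intersection of domains (>= min_overlap runs).
    """
    if set(k4_by_line) != set(k27_by_line):
        raise ValueError("H3K4me3 and H3K27me3 peak sets must cover the same lines")
    lines = sorted(k4_by_line)
    if n_required is None:
        n_required = len(lines)
    domains_by_line = {
        line: call_bivalent_per_line(k4_by_line[line], k27_by_line[line], min_overlap)
        for line in lines
    }
    merged = merge_across_lines(domains_by_line)
    if consensus_mode == "union":
        hc_biv = select_high_confidence(merged, n_required)
    elif consensus_mode == "intersection":
        iset = consensus_intersection(
            [IntervalSet(d.interval for d in domains_by_line[l]) for l in lines],
            n_required=n_required,
            min_width=min_overlap,
        )
        hc_biv = [
            ConsensusRegion(iv, CATEGORY_BIVALENT, frozenset(lines)) for iv in iset
        ]
    else:
        raise ValueError(f"unknown consensus_mode {consensus_mode!r}")
    k4only = call_exclusive_regions(
        k4_by_line, domains_by_line, min_width=min_width, n_required=n_required
    )
    k27only = call_exclusive_regions(
        k27_by_line, domains_by_line, min_width=min_width, n_required=n_required
    )
    merged = exclude_chromosomes(merged, excluded_chroms)
    hc_biv = exclude_chromosomes(hc_biv, excluded_chroms)
    k4only = exclude_chromosomes(k4only, excluded_chroms)
    k27only = exclude_chromosomes(k27only, excluded_chroms)
    _assign_region_ids(merged, "MB")
    _assign_region_ids(hc_biv, "BIV")
    _assign_region_ids(k4only, "K4O")
    _assign_region_ids(k27only, "K27O")
    return {
        "merged_bivalent": merged,
        "bivalent": hc_biv,
        "K4only": k4only,
        "K27only": k27only,
        "domains_by_line": domains_by_line,
    }
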