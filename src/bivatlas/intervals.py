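"""Exact genomic-interval set algebra.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers the bases ``start .. end-1``.  1-based inputs
(e.g. Illumina array manifests) are converted at the reader boundary.

:class:`IntervalSet` is the currency of all region logic downstream:
a per-chromosome collection of intervals which, after :meth:`~IntervalSet.normalize`,
is sorted and non-overlapping (adjacent intervals with gap 0 are merged,
strand is ignored — ChIP-seq peaks are unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "PeakSet",
    "InvalidIntervalError",
]


class InvalidIntervalError(ValueError):
    """Raised when an interval violates 0 <= start < end or has no chromosome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic span on a named chromosome, 0-based half-open.

    ``strand`` is carried for oriented features (TSS) but ignored by the
    set algebra.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvalidIntervalError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise InvalidIntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise InvalidIntervalError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


def _as_array(pairs: Sequence[Sequence[int]]) -> np.ndarray:
    arr = np.asarray(pairs, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidIntervalError("interval array must have shape (n, 2)")
    bad = np.nonzero(~((arr[:, 0] >= 0) & (arr[:, 0] < arr[:, 1])))[0]
    if bad.size:
        i = int(bad[0])
        raise InvalidIntervalError(
            f"invalid interval record {i}: start={arr[i, 0]} end={arr[i, 1]}"
        )
    return arr


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge a start-sorted (n,2) array; gap-0 adjacency merges too."""
    if len(arr) <= 1:
        return arr
    starts, ends = arr[:, 0], arr[:, 1]
    # new run begins where start > running max of previous ends
    run_end = np.maximum.accumulate(ends)
    new_run = np.empty(len(arr), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > run_end[:-1]
    idx = np.nonzero(new_run)[0]
    out = np.empty((len(idx), 2), dtype=np.int64)
    out[:, 0] = starts[idx]
    ends_of_run = np.append(idx[1:], len(arr)) - 1
    out[:, 1] = run_end[ends_of_run]
    return out


class IntervalSet:
    """Per-chromosome interval collection with exact set algebra.

    Instances are immutable from the caller's point of view; all operations
    return new sets.  Operations other than :meth:`normalize` require a
    normalized (sorted, merged) set and will normalize on the fly otherwise.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        *,
        _data: Optional[Dict[str, np.ndarray]] = None,
        _normalized: bool = False,
    ) -> None:
        if _data is not None:
            self._data = _data
            self._normalized = _normalized
            return
        data: Dict[str, List[List[int]]] = {}
        for iv in intervals:
            data.setdefault(iv.chrom, []).append([iv.start, iv.end])
        self._data = {c: _as_array(v) for c, v in data.items()}
        self._normalized = False

    # ------------------------------------------------------------------ #
    # construction helpers
    # ------------------------------------------------------------------ #
    @classmethod
    def from_arrays(cls, data: Dict[str, np.ndarray]) -> "IntervalSet":
        return cls(_data={c: _as_array(np.asarray(a)) for c, a in data.items()})

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(_data={}, _normalized=True)

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #
    @property
    def chroms(self) -> List[str]:
        return sorted(c for c, a in self._data.items() if len(a))

    def chrom_array(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in self._data[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a, b = self.normalize(), other.normalize()
        if a.chroms != b.chroms:
            return False
        return all(
            np.array_equal(a.chrom_array(c), b.chrom_array(c)) for c in a.chroms
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({len(self)} intervals on {len(self.chroms)} chroms)"

    def covered_bases(self) -> int:
        """Total number of distinct bases covered."""
        n = self.normalize()
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in n._data.values())
        )

    # ------------------------------------------------------------------ #
    # set algebra
    # ------------------------------------------------------------------ #
    def normalize(self) -> "IntervalSet":
        """Sorted, merged representation (union of overlapping/adjacent)."""
        if self._normalized:
            return self
        out = {}
        for chrom, arr in self._data.items():
            if not len(arr):
                continue
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            out[chrom] = _merge_sorted(arr[order])
        return IntervalSet(_data=out, _normalized=True)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        data: Dict[str, np.ndarray] = {}
        for chrom in set(self._data) | set(other._data):
            parts = [self.chrom_array(chrom), other.chrom_array(chrom)]
            data[chrom] = np.concatenate([p for p in parts if len(p)] or parts[:1])
        return IntervalSet(_data=data, _normalized=False).normalize()

    def intersect(self, other: "IntervalSet", min_width: int = 1) -> "IntervalSet":
        """Per-chromosome intersection keeping pieces of width >= ``min_width``."""
        if min_width < 1:
            raise ValueError("min_width must be >= 1")
        a, b = self.normalize(), other.normalize()
        out: Dict[str, np.ndarray] = {}
        for chrom in set(a._data) & set(b._data):
            pieces = _intersect_arrays(a._data[chrom], b._data[chrom])
            if len(pieces):
                keep = (pieces[:, 1] - pieces[:, 0]) >= min_width
                pieces = pieces[keep]
            if len(pieces):
                out[chrom] = pieces
        return IntervalSet(_data=out, _normalized=True)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases in self and not in other."""
        a, b = self.normalize(), other.normalize()
        out: Dict[str, np.ndarray] = {}
        for chrom, arr in a._data.items():
            barr = b.chrom_array(chrom)
            res = _subtract_arrays(arr, barr) if len(barr) else arr
            if len(res):
                out[chrom] = res
        return IntervalSet(_data=out, _normalized=True)

    def overlap_bases(self, query: GenomicInterval) -> int:
        """Number of bases of ``query`` covered by this set."""
        n = self.normalize()
        arr = n.chrom_array(query.chrom)
        if not len(arr):
            return 0
        lo = np.maximum(arr[:, 0], query.start)
        hi = np.minimum(arr[:, 1], query.end)
        return int(np.maximum(hi - lo, 0).sum())

    def overlaps_any(self, query: GenomicInterval, min_bp: int = 1) -> bool:
        """True iff total overlap of ``query`` with the set is >= ``min_bp``."""
        if min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        return self.overlap_bases(query) >= min_bp

    def filter_chroms(self, excluded: Iterable[str]) -> "IntervalSet":
        excl = set(excluded)
        return IntervalSet(
            _data={c: a for c, a in self._data.items() if c not in excl},
            _normalized=self._normalized,
        )


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection pieces of two sorted, merged (n,2) arrays (two-pointer)."""
    out: List[List[int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append([int(lo), int(hi)])
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return _as_array(out)


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a AND NOT b for sorted, merged (n,2) arrays."""
    out: List[List[int]] = []
    j = 0
    for s, e in a:
        cur = int(s)
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append([cur, int(b[k, 0])])
            cur = max(cur, int(b[k, 1]))
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append([cur, int(e)])
    return _as_array(out)


@dataclass
class PeakSet:
    """One per-cell-line, per-mark peak list (e.g. MACS output for H3K4me3).

    ``peaks`` keeps the raw records in file order; ``score``/``fdr`` are
    optional parallel sequences (narrowPeak carries a q-value column that the
    readers convert to an FDR).  ``interval_set`` is the normalized algebra
    view of the peaks.
    """

    cell_line: str
    mark: str
    peaks: List[GenomicInterval]
    score: Optional[List[float]] = None
    fdr: Optional[List[float]] = None
    _iset: Optional[IntervalSet] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.cell_line or not self.mark:
            raise ValueError("cell_line and mark must be non-empty")
        for name in ("score", "fdr"):
            vals = getattr(self, name)
            if vals is not None and len(vals) != len(self.peaks):
                raise ValueError(f"{name} length does not match peak count")

    @property
    def interval_set(self) -> IntervalSet:
        if self._iset is None:
            self._iset = IntervalSet(self.peaks).normalize()
        return self._iset

    def filter_fdr(self, fdr_max: float) -> "PeakSet":
        """Retain only peaks with FDR < ``fdr_max``; no-op if FDR absent."""
        if self.fdr is None:
            return self
        keep = [i for i, q in enumerate(self.fdr) if q < fdr_max]
        return PeakSet(
            self.cell_line,
            self.mark,
            [self.peaks[i] for i in keep],
            score=[self.score[i] for i in keep] if self.score else None,
            fdr=[self.fdr[i] for i in keep],
        )

    def __len__(self) -> int:
        return len(self.peaks)
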