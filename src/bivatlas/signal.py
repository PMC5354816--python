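"""Piecewise-constant coverage tracks (bedGraph) with exact window integrals.

A :class:`SignalTrack` stores, per chromosome, sorted non-overlapping
(start, end, value) runs plus a cumulative integral, so the sum of the
signal over any window is computed exactly (no binning error).  Values are
scaled to RPM (reads per million): raw * 1e6 / total_reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = ["SignalTrack"]


@dataclass
class _ChromTrack:
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    cum: np.ndarray  # cumulative integral up to end of each run


class SignalTrack:
    """Genome-wide piecewise-constant signal with RPM scaling."""

    def __init__(
        self,
        runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_reads: Optional[float] = None,
    ) -> None:
        self._chroms: Dict[str, _ChromTrack] = {}
        raw_total = 0.0
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e <= s):
                raise ValueError(f"empty run on {chrom}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping bedGraph runs on {chrom}")
            widths = (e - s).astype(float)
            cum = np.cumsum(v * widths)
            self._chroms[chrom] = _ChromTrack(s, e, v, cum)
            raw_total += float(cum[-1]) if len(cum) else 0.0
        self.total_reads = float(total_reads) if total_reads is not None else raw_total
        if self.total_reads <= 0:
            self.total_reads = 1.0  # degenerate all-zero track
        self.scale = 1e6 / self.total_reads

    # ------------------------------------------------------------------ #
    @classmethod
    def from_bedgraph_frame(
        cls, df: pd.DataFrame, total_reads: Optional[float] = None
    ) -> "SignalTrack":
        """Build from a DataFrame with columns chrom, start, end, value."""
        runs = {}
        for chrom, grp in df.groupby("chrom"):
            runs[str(chrom)] = (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp["value"].to_numpy(),
            )
        return cls(runs, total_reads=total_reads)

    def to_bedgraph_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self._chroms):
            t = self._chroms[chrom]
            for s, e, v in zip(t.starts, t.ends, t.values):
                rows.append((chrom, int(s), int(e), float(v)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    # ------------------------------------------------------------------ #
    def raw_integral(self, chrom: str, a: int, b: int) -> float:
        """Integral of the raw (unscaled) signal over [a, b)."""
        if b <= a:
            return 0.0
        t = self._chroms.get(chrom)
        if t is None:
            return 0.0
        i = int(np.searchsorted(t.ends, a, side="right"))
        j = int(np.searchsorted(t.starts, b, side="left"))
        if i >= j:
            return 0.0
        total = float(t.cum[j - 1] - (t.cum[i - 1] if i > 0 else 0.0))
        # clip partial overlap at both edges
        left_clip = max(0, a - int(t.starts[i]))
        total -= left_clip * float(t.values[i])
        right_clip = max(0, int(t.ends[j - 1]) - b)
        total -= right_clip * float(t.values[j - 1])
        return total

    def rpm_sum(self, chrom: str, a: int, b: int) -> float:
        """Summed RPM signal (per-base values added up) over [a, b)."""
        return self.raw_integral(chrom, a, b) * self.scale

    def rpm_mean(self, chrom: str, a: int, b: int) -> float:
        """Mean RPM signal over [a, b)."""
        if b <= a:
            return 0.0
        return self.rpm_sum(chrom, a, b) / (b - a)

    def window_sum(self, interval: GenomicInterval, flank: int = 0) -> float:
        return self.rpm_sum(
            interval.chrom, max(0, interval.start - flank), interval.end + flank
        )
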