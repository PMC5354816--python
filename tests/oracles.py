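"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's interval algebra: interval sets are
materialized as per-base boolean arrays and operations become elementwise
boolean logic plus run-length extraction.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np


def bool_cover(intervals: np.ndarray, length: int) -> np.ndarray:
    """Per-base coverage mask of (n, 2) start/end pairs on [0, length)."""
    mask = np.zeros(length, dtype=bool)
    for s, e in np.asarray(intervals, dtype=int).reshape(-1, 2):
        mask[max(0, s) : min(length, e)] = True
    return mask


def runs(mask: np.ndarray) -> np.ndarray:
    """Maximal True runs of a boolean mask as an (n, 2) array."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return np.stack([starts, ends], axis=1) if len(starts) else np.empty((0, 2), int)


def width_filter(arr: np.ndarray, min_width: int) -> np.ndarray:
    if not len(arr):
        return arr
    return arr[(arr[:, 1] - arr[:, 0]) >= min_width]


def random_intervals(
    rng: np.random.Generator, n: int, length: int, max_width: int = 2000
) -> np.ndarray:
    starts = rng.integers(0, length - 1, size=n)
    widths = rng.integers(1, max_width, size=n)
    ends = np.minimum(starts + widths, length)
    return np.stack([starts, ends], axis=1)


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """q_i = min_{k: p_k >= p_i in rank order} p_(k) * m / k, straight from
    the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pearson_chi2_2x2(a: int, na: int, b: int, nb: int) -> float:
    """Closed-form Pearson chi-squared for a 2x2 occupancy table."""
    obs = np.array([[a, na - a], [b, nb - b]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    exp = rows * cols / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())
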