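"""Small interval-arithmetic helpers shared by the caller and enrichment stages.

All coordinates are 0-based half-open. Interval sets handled here are
assumed sorted and non-overlapping within a chromosome (domain callers
produce them in that form; readers validate).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "coverage_upto",
    "overlap_per_query",
    "points_in_intervals",
    "intersect_total",
]


def coverage_upto(starts: np.ndarray, ends: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Total covered bp in [0, x) for a sorted non-overlapping interval set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    x = np.asarray(x, dtype=np.int64)
    if starts.size == 0:
        return np.zeros_like(x)
    lengths = ends - starts
    cum = np.concatenate(([0], np.cumsum(lengths)))
    idx = np.searchsorted(starts, x, side="right")  # intervals with start < x
    partial = np.clip(x - starts[np.maximum(idx - 1, 0)], 0, lengths[np.maximum(idx - 1, 0)])
    partial = np.where(idx > 0, partial, 0)
    return cum[np.maximum(idx - 1, 0)] * (idx > 0) + partial


def overlap_per_query(
    q_starts: np.ndarray, q_ends: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Overlap in bp of each query interval with a sorted non-overlapping set."""
    return coverage_upto(starts, ends, q_ends) - coverage_upto(starts, ends, q_starts)


def points_in_intervals(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: is each point inside any interval of a sorted set."""
    points = np.asarray(points)
    if len(starts) == 0:
        return np.zeros(points.shape, dtype=bool)
    bounds = np.empty(2 * len(starts), dtype=np.int64)
    bounds[0::2] = starts
    bounds[1::2] = ends
    idx = np.searchsorted(bounds, points, side="right")
    return idx % 2 == 1


def intersect_total(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> int:
    """Total bp shared between two sorted non-overlapping interval sets."""
    return int(np.sum(overlap_per_query(a_starts, a_ends, b_starts, b_ends)))
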