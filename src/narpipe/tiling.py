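"""Probe-level tiling-signal processing.

Turns replicated IP/input probe intensities into the smoothed log2-ratio
profile consumed by the domain caller: quantile normalization across
samples, replicate averaging on the linear scale, log2(IP/input) per probe,
and centred sliding-window smoothing that never crosses a chromosome
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ProbeTrack",
    "BindingProfile",
    "quantile_normalize",
    "ratio_profile",
    "smooth",
]


def chrom_slices(chroms: np.ndarray) -> list[tuple[str, slice]]:
    """Contiguous per-chromosome slices of a probe table, in first-appearance order.

    Raises if rows of the same chromosome are not contiguous.
    """
    chroms = np.asarray(chroms)
    if chroms.size == 0:
        return []
    boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [chroms.size]))
    names = [str(chroms[s]) for s in starts]
    if len(set(names)) != len(names):
        raise ValueError("chromosome blocks are not contiguous")
    return [(n, slice(int(s), int(e))) for n, s, e in zip(names, starts, ends)]


def _check_positions(chroms: np.ndarray, positions: np.ndarray) -> None:
    if len(chroms) != len(positions):
        raise ValueError("chroms and positions must have equal length")
    for _, sl in chrom_slices(chroms):
        pos = positions[sl]
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("probe positions must be strictly increasing within a chromosome")


@dataclass
class ProbeTrack:
    """Probe intensities for one channel (IP or input) across replicates.

    ``intensities`` has shape (n_probes, n_replicates); all values must be
    positive (linear scale, post-normalization).
    """

    chroms: np.ndarray
    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[0] != len(self.positions):
            if self.intensities.shape[1] == len(self.positions):
                self.intensities = self.intensities.T
            else:
                raise ValueError("intensity matrix does not match probe count")
        _check_positions(self.chroms, self.positions)
        if self.intensities.shape[1] < 1:
            raise ValueError("at least one replicate required")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be strictly positive")

    @property
    def n_probes(self) -> int:
        return len(self.positions)

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[1]


@dataclass
class BindingProfile:
    """Per-probe log2(ChIP/input) ratios for one sample.

    ``smoothed`` holds the sliding-window mean of ``log2_ratio``; a probe is
    *positive* iff its smoothed value exceeds zero.
    """

    chroms: np.ndarray
    positions: np.ndarray
    log2_ratio: np.ndarray
    smoothed: np.ndarray = field(default=None)  # type: ignore[assignment]
    spacing: int | None = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if self.smoothed is None:
            self.smoothed = self.log2_ratio.copy()
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        if not (len(self.chroms) == len(self.positions) == len(self.log2_ratio) == len(self.smoothed)):
            raise ValueError("all per-probe vectors must have equal length")
        _check_positions(self.chroms, self.positions)

    @property
    def is_positive(self) -> np.ndarray:
        return self.smoothed > 0

    @property
    def n_probes(self) -> int:
        return len(self.positions)

    def by_chromosome(self) -> list[tuple[str, slice]]:
        return chrom_slices(self.chroms)

    def probe_spacing(self) -> int:
        """Declared probe spacing, or the median inter-probe gap if undeclared."""
        if self.spacing is not None:
            return int(self.spacing)
        gaps = []
        for _, sl in self.by_chromosome():
            pos = self.positions[sl]
            if pos.size > 1:
                gaps.append(np.diff(pos))
        if not gaps:
            raise ValueError("cannot infer probe spacing from fewer than two probes")
        return int(np.median(np.concatenate(gaps)))


def quantile_normalize(intensities: np.ndarray) -> np.ndarray:
    """Force identical marginal distributions on the columns of a matrix.

    Each column is replaced by the across-column mean of rank-matched
    values; ties within a column receive the average of the reference
    values they span. Rank order within each column is preserved.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (probes x samples) matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite values are not allowed")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        col = np.empty(n)
        col[order] = reference
        # average reference values over tied input values
        ranks = rankdata(x[:, j], method="dense") - 1
        sums = np.bincount(ranks, weights=col)
        counts = np.bincount(ranks)
        col = (sums / counts)[ranks]
        out[:, j] = col
    return out


def ratio_profile(ip: ProbeTrack, input_: ProbeTrack) -> BindingProfile:
    """log2 of (mean IP intensity / mean input intensity) per probe.

    Replicates are averaged on the linear scale before taking the log.
    The two tracks must share an identical probe grid.
    """
    if ip.n_probes != input_.n_probes or np.any(ip.positions != input_.positions) or np.any(
        ip.chroms != input_.chroms
    ):
        raise ValueError("IP and input tracks must share the same probe grid")
    ip_mean = ip.intensities.mean(axis=1)
    in_mean = input_.intensities.mean(axis=1)
    if np.any(ip_mean <= 0) or np.any(in_mean <= 0):
        raise ValueError("non-positive mean intensity")
    ratio = np.log2(ip_mean / in_mean)
    return BindingProfile(ip.chroms.copy(), ip.positions.copy(), ratio)


def smooth(profile: BindingProfile, window_bp: int = 500) -> BindingProfile:
    """Mean of raw ratios within ``window_bp`` centred on each probe start.

    Window membership is by probe start position, inclusive at both edges;
    the window is truncated at chromosome ends and never crosses into a
    neighbouring chromosome.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp / 2.0
    smoothed = np.empty(profile.n_probes)
    for _, sl in profile.by_chromosome():
        pos = profile.positions[sl]
        val = profile.log2_ratio[sl]
        cs = np.concatenate(([0.0], np.cumsum(val)))
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        smoothed[sl] = (cs[hi] - cs[lo]) / (hi - lo)
    return replace(profile, smoothed=smoothed)
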