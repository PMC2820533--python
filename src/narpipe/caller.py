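"""Detection of nucleoporin-associated regions (NARs) from smoothed binding profiles.

The caller slides a fixed-width window along each chromosome, centred on
each probe start, and scores the fraction of probes in the window whose
smoothed log2 ratio is positive. Maximal runs of probes whose window
density exceeds the threshold become domains. Also provided: a label
shuffle for the randomization null, a two-stage seed-and-extend
alternative caller, interval overlap reports, and occupancy summaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import intersect_total, points_in_intervals
from .tiling import BindingProfile

__all__ = [
    "DensityTrack",
    "DomainSet",
    "positive_probe_density",
    "call_domains",
    "call_domains_two_stage",
    "shuffle_binding",
    "domain_overlap",
    "occupancy_stats",
]

DOMAIN_COLUMNS = ["chrom", "start", "end", "n_probes", "mean_ratio", "mean_density"]


@dataclass
class DensityTrack:
    """Per-probe fraction of positively bound probes in a centred window."""

    chroms: np.ndarray
    positions: np.ndarray
    density: np.ndarray
    window_bp: int
    smoothed: np.ndarray | None = None
    spacing: int | None = None

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size and (self.density.min() < 0 or self.density.max() > 1):
            raise ValueError("density values must lie in [0, 1]")


@dataclass
class DomainSet:
    """Called domains: sorted, non-overlapping intervals with per-domain stats."""

    domains: pd.DataFrame
    theta: float
    window_bp: int

    def __post_init__(self) -> None:
        df = self.domains
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"domain table missing columns: {missing}")
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if np.any(e <= s):
                raise ValueError("domains must have end > start")
            if len(s) > 1 and np.any(s[1:] < e[:-1]):
                raise ValueError(f"domains overlap or are unsorted on {chrom}")

    def __len__(self) -> int:
        return len(self.domains)

    @property
    def total_bp(self) -> int:
        if len(self.domains) == 0:
            return 0
        return int((self.domains["end"] - self.domains["start"]).sum())

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.domains[self.domains["chrom"] == chrom]
        return sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.domains["chrom"]))


def positive_probe_density(profile: BindingProfile, window_bp: int = 10_000) -> DensityTrack:
    """Fraction of positive probes in a window centred on each probe start.

    Windows are truncated at chromosome ends; membership is by probe start
    position, inclusive at both edges.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp / 2.0
    density = np.empty(profile.n_probes)
    pos_flag = profile.is_positive.astype(float)
    for _, sl in profile.by_chromosome():
        pos = profile.positions[sl]
        cs = np.concatenate(([0.0], np.cumsum(pos_flag[sl])))
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        density[sl] = (cs[hi] - cs[lo]) / (hi - lo)
    spacing = None
    try:
        spacing = profile.probe_spacing()
    except ValueError:
        pass
    return DensityTrack(
        profile.chroms, profile.positions, density, window_bp,
        smoothed=profile.smoothed, spacing=spacing,
    )


def _runs(mask: np.ndarray, max_gap: int = 0) -> list[tuple[int, int]]:
    """Maximal [first, last] index runs of True, bridging gaps of <= max_gap False."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _domains_from_mask(
    density: DensityTrack,
    mask: np.ndarray,
    theta: float,
    max_gap_probes: int,
    extent: str,
) -> DomainSet:
    from .tiling import chrom_slices

    if extent not in ("probes", "windows"):
        raise ValueError("extent must be 'probes' or 'windows'")
    spacing = density.spacing if density.spacing is not None else 35
    half = density.window_bp // 2
    records = []
    for chrom, sl in chrom_slices(density.chroms):
        pos = density.positions[sl]
        dens = density.density[sl]
        sm = density.smoothed[sl] if density.smoothed is not None else None
        for i0, i1 in _runs(mask[sl], max_gap_probes):
            if extent == "probes":
                start = int(pos[i0])
                end = int(pos[i1]) + spacing
            else:
                start = max(0, int(pos[i0]) - half)
                end = int(pos[i1]) + half
            records.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_probes": i1 - i0 + 1,
                    "mean_ratio": float(np.mean(sm[i0 : i1 + 1])) if sm is not None else np.nan,
                    "mean_density": float(np.mean(dens[i0 : i1 + 1])),
                }
            )
    df = pd.DataFrame.from_records(records, columns=DOMAIN_COLUMNS)
    return DomainSet(df, theta=theta, window_bp=density.window_bp)


def call_domains(
    density: DensityTrack,
    theta: float = 0.70,
    max_gap_probes: int = 0,
    extent: str = "probes",
) -> DomainSet:
    """Group probes whose window density strictly exceeds ``theta`` into domains.

    A domain spans [first qualifying probe start, last qualifying probe
    start + spacing); with ``extent='windows'`` the union of the qualifying
    probes' windows is reported instead (clipped at 0).
    """
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    return _domains_from_mask(density, density.density > theta, theta, max_gap_probes, extent)


def call_domains_two_stage(
    density: DensityTrack,
    seed_theta: float = 0.80,
    extend_theta: float = 0.60,
    max_gap_probes: int = 0,
    extent: str = "probes",
) -> DomainSet:
    """Seed-and-extend caller: strict seeds extended while density stays high.

    Stage 1 marks probes with density > ``seed_theta``; stage 2 extends
    each seed outward through probes with density > ``extend_theta``;
    extensions that meet are merged.
    """
    for t in (seed_theta, extend_theta):
        if not 0 < t < 1:
            raise ValueError("thresholds must lie in (0, 1)")
    if extend_theta > seed_theta:
        raise ValueError("extend_theta must not exceed seed_theta")
    seeds = density.density > seed_theta
    extendable = density.density > extend_theta
    keep = np.zeros_like(extendable)
    for i0, i1 in _runs(extendable, max_gap_probes):
        if seeds[i0 : i1 + 1].any():
            keep[i0 : i1 + 1] = True
    return _domains_from_mask(density, keep, seed_theta, max_gap_probes, extent)


def shuffle_binding(profile: BindingProfile, seed: int) -> BindingProfile:
    """Permute probe values (hence positive/negative labels) across positions.

    Positions stay fixed; the multiset of smoothed values (and therefore the
    genome-wide count of positives) is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(profile.n_probes)
    return dataclasses.replace(
        profile,
        log2_ratio=profile.log2_ratio[perm],
        smoothed=profile.smoothed[perm],
    )


def domain_overlap(a: DomainSet, b: DomainSet, genome: dict[str, int] | None = None) -> dict:
    """Base-pair overlap report between two domain sets on the same genome.

    Returns shared bp, the fraction of each set covered by the other, and
    the bp Jaccard index. If ``genome`` is given, domains on chromosomes
    outside it are rejected.
    """
    if genome is not None:
        known = set(genome)
        for ds, name in ((a, "a"), (b, "b")):
            extra = set(ds.chromosomes) - known
            if extra:
                raise ValueError(f"domain set {name} has chromosomes not in genome: {sorted(extra)}")
    shared = 0
    for chrom in set(a.chromosomes) | set(b.chromosomes):
        a_s, a_e = a.intervals(chrom)
        b_s, b_e = b.intervals(chrom)
        shared += intersect_total(a_s, a_e, b_s, b_e)
    a_bp, b_bp = a.total_bp, b.total_bp
    union = a_bp + b_bp - shared
    return {
        "shared_bp": shared,
        "fraction_a_in_b": shared / a_bp if a_bp else 0.0,
        "fraction_b_in_a": shared / b_bp if b_bp else 0.0,
        "jaccard": shared / union if union else 0.0,
    }


def probe_agreement(a: DomainSet, b: DomainSet, chroms: np.ndarray, positions: np.ndarray) -> float:
    """Fraction of probes classified as in-domain by ``b`` that ``a`` also covers."""
    from .tiling import chrom_slices

    in_a = np.zeros(len(positions), dtype=bool)
    in_b = np.zeros(len(positions), dtype=bool)
    for chrom, sl in chrom_slices(np.asarray(chroms, dtype=object)):
        a_s, a_e = a.intervals(chrom)
        b_s, b_e = b.intervals(chrom)
        in_a[sl] = points_in_intervals(positions[sl], a_s, a_e)
        in_b[sl] = points_in_intervals(positions[sl], b_s, b_e)
    if not in_b.any():
        return float("nan")
    return float(np.sum(in_a & in_b) / np.sum(in_b))


def occupancy_stats(
    domains: DomainSet,
    genome: dict[str, int],
    grouping: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-group % bp occupancy, domain counts, and length quartiles.

    ``grouping`` maps group names to chromosome lists and must partition the
    genome (e.g. {'X': ['X'], 'autosomes': ['2L', '2R', ...]}); by default
    every chromosome is its own group plus a 'genome' total.
    """
    for chrom in domains.chromosomes:
        if chrom not in genome:
            raise ValueError(f"domain chromosome {chrom!r} not in genome")
        s, e = domains.intervals(chrom)
        if len(s) and (s.min() < 0 or e.max() > genome[chrom]):
            raise ValueError(f"domain outside chromosome bounds on {chrom}")
    if grouping is None:
        grouping = {c: [c] for c in genome}
        grouping["genome"] = list(genome)
    else:
        listed = [c for chroms in grouping.values() for c in chroms]
        if sorted(listed) != sorted(genome):
            raise ValueError("grouping must partition the genome's chromosomes")
    rows = []
    for group, chroms in grouping.items():
        sub = domains.domains[domains.domains["chrom"].isin(chroms)]
        lengths = (sub["end"] - sub["start"]).to_numpy()
        genome_bp = sum(genome[c] for c in chroms)
        rows.append(
            {
                "group": group,
                "n_domains": len(sub),
                "domain_bp": int(lengths.sum()),
                "occupancy_pct": 100.0 * lengths.sum() / genome_bp if genome_bp else 0.0,
                "median_length": float(np.median(lengths)) if len(lengths) else np.nan,
                "q1_length": float(np.percentile(lengths, 25)) if len(lengths) else np.nan,
                "q3_length": float(np.percentile(lengths, 75)) if len(lengths) else np.nan,
            }
        )
    return pd.DataFrame(rows)
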