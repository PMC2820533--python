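"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates evenly spaced tiling-probe layouts, binding profiles with planted
high-density domains, gene tables whose expression labels depend on domain
membership, and voxelized three-channel nucleus image stacks (DAPI, lamin,
FISH). Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tiling import BindingProfile

__all__ = [
    "GenomeSpec",
    "PlantedDomain",
    "NucleusSpec",
    "NucleusStack",
    "generate_probe_layout",
    "generate_binding_profile",
    "generate_gene_table",
    "generate_nucleus_stack",
]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "expressed", "de_status"]


@dataclass
class GenomeSpec:
    """Chromosome sizes and probe spacing for a synthetic tiling array."""

    chromosomes: list[tuple[str, int]]
    probe_spacing: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class PlantedDomain:
    """A region where probes are positive with elevated probability ``p_in``."""

    chromosome: str
    start: int
    end: int
    p_in: float
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")


@dataclass
class NucleusSpec:
    """Parameters of a simulated spherical nucleus with a spherical FISH signal.

    ``signal_center`` is the normalized boundary distance of the signal
    centre (0 = on the boundary, 1 = at the centroid); ``signal_extent`` is
    the signal-sphere radius as a fraction of the nuclear radius.
    """

    radius: int = 25
    voxel_size: float = 0.1
    signal_mode: str = "custom"
    signal_center: float = 0.0
    signal_extent: float = 0.30
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius < 8:
            raise ValueError("radius must be at least 8 voxels")
        if self.signal_mode == "peripheral":
            self.signal_center = 0.0
        elif self.signal_mode == "interior":
            self.signal_center = 0.5
        elif self.signal_mode != "custom":
            raise ValueError("signal_mode must be peripheral, interior or custom")
        if not 0 <= self.signal_center <= 1:
            raise ValueError("signal_center must lie in [0, 1]")
        if not 0 < self.signal_extent <= 1:
            raise ValueError("signal_extent must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class NucleusStack:
    """Three co-registered voxel channels for one nucleus."""

    dapi: np.ndarray
    lamin: np.ndarray
    fish: np.ndarray
    voxel_size: float = 0.1

    def __post_init__(self) -> None:
        if not (self.dapi.shape == self.lamin.shape == self.fish.shape):
            raise ValueError("channels must have identical shapes")
        for ch in (self.dapi, self.lamin, self.fish):
            if np.any(ch < 0):
                raise ValueError("intensities must be non-negative")


def generate_probe_layout(spec: GenomeSpec) -> pd.DataFrame:
    """Evenly spaced probe start positions, one row per probe.

    Each chromosome gets floor(length / spacing) probes starting at 0.
    """
    frames = []
    for name, length in spec.chromosomes:
        n = length // spec.probe_spacing
        frames.append(
            pd.DataFrame(
                {"chrom": name, "position": np.arange(n, dtype=np.int64) * spec.probe_spacing}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _check_domains(layout: pd.DataFrame, domains: list[PlantedDomain], lengths: dict[str, int]) -> None:
    by_chrom: dict[str, list[PlantedDomain]] = {}
    for d in domains:
        if d.chromosome not in lengths:
            raise ValueError(f"planted domain on unknown chromosome {d.chromosome!r}")
        if d.start < 0 or d.end > lengths[d.chromosome]:
            raise ValueError("planted domain outside chromosome bounds")
        by_chrom.setdefault(d.chromosome, []).append(d)
    for chrom, ds in by_chrom.items():
        ds = sorted(ds, key=lambda d: d.start)
        for prev, nxt in zip(ds, ds[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping planted domains on {chrom}")


def generate_binding_profile(
    layout: pd.DataFrame,
    domains: list[PlantedDomain],
    p_out: float = 0.0,
    seed: int = 0,
    spacing: int | None = None,
    ratio_scale: float = 0.5,
    lengths: dict[str, int] | None = None,
) -> BindingProfile:
    """Bernoulli positive labels with half-normal log2 ratios of matching sign.

    A probe inside a planted domain is positive with that domain's ``p_in``,
    otherwise with the global ``p_out``. Positive probes draw a half-normal
    ratio above 0 and negative probes below 0 (scale ``ratio_scale``); only
    the sign matters downstream.
    """
    if not 0 <= p_out <= 1:
        raise ValueError("p_out must lie in [0, 1]")
    if lengths is None:
        lengths = {
            str(c): int(sub["position"].max()) + (spacing or 35)
            for c, sub in layout.groupby("chrom", sort=False)
        }
    _check_domains(layout, domains, lengths)
    rng = np.random.default_rng(seed)
    chroms = layout["chrom"].to_numpy(dtype=object)
    positions = layout["position"].to_numpy(np.int64)
    p = np.full(len(positions), p_out, dtype=float)
    for d in domains:
        sel = (chroms == d.chromosome) & (positions >= d.start) & (positions < d.end)
        p[sel] = d.p_in
    positive = rng.random(len(p)) < p
    magnitude = np.abs(rng.normal(0.0, ratio_scale, len(p)))
    # strictly non-zero so the sign is unambiguous
    magnitude = np.maximum(magnitude, 1e-9)
    ratio = np.where(positive, magnitude, -magnitude)
    return BindingProfile(chroms, positions, ratio, smoothed=ratio.copy(), spacing=spacing)


def generate_gene_table(
    layout: pd.DataFrame,
    domains: list[PlantedDomain],
    n_genes: int,
    p_expr_in: float = 0.63,
    p_expr_out: float = 0.40,
    p_down_in: float = 0.29,
    p_down_out: float = 0.19,
    p_up: float = 0.05,
    gene_length: int = 2_000,
    gene_gap: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Non-overlapping genes whose expression call depends on domain membership.

    Genes are placed on a regular slot grid (length + gap) and a random
    subset of slots is used. A gene counts as inside a domain when more
    than half of its length is covered. Expression defaults encode the
    observed 63% (inside) vs 40% (outside) expressed fractions; the
    differential-expression label draws 'down' with higher probability
    inside domains.
    """
    for p in (p_expr_in, p_expr_out, p_down_in, p_down_out, p_up):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if n_genes == 0:
        return pd.DataFrame(columns=GENE_COLUMNS)
    slot = gene_length + gene_gap
    chrom_span = {
        str(c): int(sub["position"].max()) + slot for c, sub in layout.groupby("chrom", sort=False)
    }
    slots = []
    for chrom, span in chrom_span.items():
        n_slots = span // slot
        for i in range(n_slots):
            slots.append((chrom, i * slot))
    if n_genes > len(slots):
        raise ValueError(f"requested {n_genes} genes but genome only holds {len(slots)}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(slots), size=n_genes, replace=False))
    records = []
    from .intervals import overlap_per_query

    dom_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for d in domains:
        s, e = dom_by_chrom.setdefault(d.chromosome, ([], []))  # type: ignore[assignment]
        s.append(d.start)  # type: ignore[union-attr]
        e.append(d.end)  # type: ignore[union-attr]
    dom_by_chrom = {
        c: (np.sort(np.asarray(s)), np.asarray(e)[np.argsort(s)]) for c, (s, e) in dom_by_chrom.items()
    }
    for k, idx in enumerate(chosen):
        chrom, start = slots[idx]
        end = start + gene_length
        if chrom in dom_by_chrom:
            ds, de = dom_by_chrom[chrom]
            ov = int(overlap_per_query(np.array([start]), np.array([end]), ds, de)[0])
        else:
            ov = 0
        inside = ov > gene_length / 2
        expressed = bool(rng.random() < (p_expr_in if inside else p_expr_out))
        u = rng.random()
        p_down = p_down_in if inside else p_down_out
        de_status = "down" if u < p_down else ("up" if u < p_down + p_up else "unchanged")
        records.append(
            {
                "gene_id": f"g{k:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "expressed": expressed,
                "de_status": de_status,
            }
        )
    return pd.DataFrame.from_records(records, columns=GENE_COLUMNS)


def generate_nucleus_stack(spec: NucleusSpec) -> NucleusStack:
    """Voxelized spherical nucleus with lamin shell and a spherical FISH signal.

    DAPI is a filled sphere plus Gaussian noise; lamin is a one-voxel shell
    at the sphere surface; the FISH signal is a filled sphere of radius
    ``signal_extent * radius`` whose centre sits at normalized boundary
    distance ``signal_center`` in a random (seeded) direction. Voxels of the
    signal falling outside the nucleus are kept in the image (downstream
    masking removes them).
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.radius
    pad = 4
    n = 2 * (r + pad) + 1
    c = r + pad
    zz, yy, xx = np.indices((n, n, n))
    dist = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
    nucleus = dist <= r
    shell = nucleus & (dist > r - 1)

    # signal centre: at distance (1 - signal_center) * r from the centroid,
    # in a uniformly random direction
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    sc = np.array([c, c, c]) + (1.0 - spec.signal_center) * r * v
    sig_r = spec.signal_extent * r
    sig_dist = np.sqrt((zz - sc[0]) ** 2 + (yy - sc[1]) ** 2 + (xx - sc[2]) ** 2)
    signal = sig_dist <= sig_r
    if not (signal & nucleus).any():
        raise ValueError("signal sphere lies entirely outside the nucleus")

    background, foreground = 10.0, 110.0

    def channel(mask: np.ndarray) -> np.ndarray:
        img = np.full((n, n, n), background)
        img[mask] = foreground
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        return np.clip(img, 0.0, None).astype(np.float32)

    return NucleusStack(
        dapi=channel(nucleus), lamin=channel(shell), fish=channel(signal),
        voxel_size=spec.voxel_size,
    )
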