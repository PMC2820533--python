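"""Nucleus segmentation and FISH-signal distance measurement in 3D stacks.

The boundary of each nucleus is segmented from the DAPI channel by Otsu
thresholding (largest connected component, slice-wise hole filling),
optionally refined against a single-voxel lamin rim, and converted into a
Euclidean distance-to-boundary map. FISH voxels inside the mask are
thresholded and their distances summarised per nucleus, normalized by the
nuclear radius so that 0 is the boundary and 1 the centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "NucleusMask",
    "FishMeasurement",
    "segment_nucleus",
    "refine_boundary",
    "distance_map",
    "extract_fish_distances",
    "estimate_radius",
    "normalize_distance",
    "measure_stack",
]


@dataclass
class NucleusMask:
    """Segmented nuclear volume with centroid, mean radius, and QC flags."""

    mask: np.ndarray
    centroid: tuple[float, float, float]
    radius_voxels: float
    voxel_size: float = 1.0
    rim: np.ndarray | None = None
    rim_radius_voxels: float | None = None
    flagged_fraction: float | None = None
    usable: bool = True

    @property
    def radius_um(self) -> float:
        return self.radius_voxels * self.voxel_size


@dataclass
class FishMeasurement:
    """Per-nucleus distance summary for one FISH locus."""

    locus_id: str
    nucleus_id: int
    voxel_distances: np.ndarray
    mean_distance: float
    radius_voxels: float
    normalized_mean: float
    usable: bool = True

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_distances)


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def estimate_radius(mask: np.ndarray, centroid: tuple[float, ...] | None = None) -> float:
    """Mean distance (voxels) from surface voxels to the mask centroid."""
    if centroid is None:
        centroid = ndimage.center_of_mass(mask)
    surf = np.argwhere(_surface(mask))
    return float(np.mean(np.linalg.norm(surf - np.asarray(centroid), axis=1)))


def segment_nucleus(dapi: np.ndarray, voxel_size: float = 1.0) -> NucleusMask:
    """Otsu-threshold the DAPI channel and keep the largest connected component.

    Holes are filled slice-wise along the first (z) axis.
    """
    dapi = np.asarray(dapi)
    if np.ptp(dapi) == 0:
        raise ValueError("constant DAPI image: cannot threshold")
    thr = threshold_otsu(dapi)
    fg = dapi > thr
    if not fg.any():
        raise ValueError("no foreground voxels after thresholding")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    for z in range(fg.shape[0]):
        fg[z] = ndimage.binary_fill_holes(fg[z])
    centroid = ndimage.center_of_mass(fg)
    radius = estimate_radius(fg, centroid)
    return NucleusMask(mask=fg, centroid=tuple(centroid), radius_voxels=radius, voxel_size=voxel_size)


def refine_boundary(
    mask: NucleusMask,
    lamin: np.ndarray,
    tolerance: float = 2.0,
    max_flagged: float = 0.10,
) -> NucleusMask:
    """Check the DAPI boundary against a thinned lamin rim, flagging deviations.

    The lamin channel is Otsu-thresholded and thinned slice-wise to a
    single-voxel rim. Surface voxels of the DAPI mask farther than
    ``tolerance`` voxels from the rim are flagged; the nucleus is marked
    unusable when more than ``max_flagged`` of its surface is flagged.
    An empty rim skips refinement with a warning.
    """
    lamin = np.asarray(lamin)
    if np.ptp(lamin) == 0:
        warnings.warn("constant lamin channel: skipping boundary refinement")
        return mask
    rim_mask = lamin > threshold_otsu(lamin)
    rim = np.zeros_like(rim_mask)
    for z in range(rim_mask.shape[0]):
        if rim_mask[z].any():
            rim[z] = skeletonize(rim_mask[z])
    if not rim.any():
        warnings.warn("empty lamin rim: skipping boundary refinement")
        return mask
    dist_to_rim = ndimage.distance_transform_edt(~rim)
    surface = _surface(mask.mask)
    flagged = dist_to_rim[surface] > tolerance
    frac = float(flagged.mean())
    rim_radius = float(
        np.mean(np.linalg.norm(np.argwhere(rim) - np.asarray(mask.centroid), axis=1))
    )
    return replace(
        mask,
        rim=rim,
        rim_radius_voxels=rim_radius,
        flagged_fraction=frac,
        usable=frac <= max_flagged,
    )


def distance_map(mask: NucleusMask | np.ndarray) -> np.ndarray:
    """Euclidean distance of each inside voxel to the nearest outside voxel.

    Outside voxels are 0. This is the distance to the closest point on the
    nuclear boundary, which is the quantity the per-voxel measurements use.
    """
    m = mask.mask if isinstance(mask, NucleusMask) else np.asarray(mask, dtype=bool)
    return ndimage.distance_transform_edt(m)


def _fish_threshold(values: np.ndarray) -> float:
    """Otsu threshold, iterated when the classes are badly unbalanced.

    A small bright spot in a large background makes plain Otsu split the
    background noise instead of isolating the spot; when the foreground
    class is not well separated from the background, Otsu is re-applied to
    the foreground until it is.
    """
    thr = float(threshold_otsu(values))
    for _ in range(5):
        fg = values[values > thr]
        bg = values[values <= thr]
        if fg.size < 2 or bg.size == 0:
            break
        if fg.mean() >= bg.mean() + 0.5 * (values.max() - bg.mean()):
            break
        thr = float(threshold_otsu(fg))
    return thr


def extract_fish_distances(
    fish: np.ndarray,
    mask: NucleusMask,
    dmap: np.ndarray,
    threshold: float | str = "otsu",
    locus_id: str = "",
    nucleus_id: int = 0,
) -> FishMeasurement:
    """Distances of thresholded FISH voxels inside the nucleus to the boundary.

    The threshold is computed by Otsu on the FISH intensities restricted to
    the mask (or passed explicitly). Raises when no FISH voxel falls inside
    the nucleus, so callers can exclude the nucleus with a diagnostic.
    """
    fish = np.asarray(fish)
    inside = mask.mask
    if threshold == "otsu":
        thr = _fish_threshold(fish[inside])
    else:
        thr = float(threshold)
    sig = (fish > thr) & inside
    if not sig.any():
        raise ValueError(f"no FISH voxels inside the nucleus (locus {locus_id!r})")
    dists = dmap[sig]
    mean_d = float(dists.mean())
    return FishMeasurement(
        locus_id=locus_id,
        nucleus_id=nucleus_id,
        voxel_distances=dists,
        mean_distance=mean_d,
        radius_voxels=mask.radius_voxels,
        normalized_mean=normalize_distance(mean_d, mask.radius_voxels),
        usable=mask.usable,
    )


def normalize_distance(distance: float, radius: float) -> float:
    """Distance as a fraction of the nuclear radius (0 boundary, 1 centroid)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return float(distance) / float(radius)


def measure_stack(
    stack,
    locus_id: str = "",
    nucleus_id: int = 0,
    tolerance: float = 2.0,
    refine: bool = True,
) -> FishMeasurement:
    """Full per-nucleus pipeline: segment, refine, distance map, FISH distances."""
    mask = segment_nucleus(stack.dapi, voxel_size=stack.voxel_size)
    if refine:
        mask = refine_boundary(mask, stack.lamin, tolerance=tolerance)
    dmap = distance_map(mask)
    return extract_fish_distances(
        stack.fish, mask, dmap, locus_id=locus_id, nucleus_id=nucleus_id
    )
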