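"""Plain-text genomic I/O: bedGraph and BED, plus TIFF stacks for nuclei.

All coordinates are 0-based half-open on disk and in memory. Readers skip
comment/track lines, validate per line, and report the offending line
number on malformed input.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .caller import DOMAIN_COLUMNS, DomainSet
from .tiling import BindingProfile

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "profile_to_bedgraph",
    "bedgraph_to_profile",
    "read_bed",
    "write_bed",
    "domains_to_bed",
    "bed_to_domains",
    "read_gene_table",
    "write_gene_table",
    "read_stack",
    "write_stack",
]

_SKIP_PREFIXES = ("#", "track", "browser")


def _parse_lines(path: str, n_fields_min: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < n_fields_min:
                raise ValueError(f"{path}:{lineno}: expected >= {n_fields_min} fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            yield lineno, fields


def read_bedgraph(path: str) -> pd.DataFrame:
    """4-column bedGraph -> DataFrame(chrom, start, end, value); rejects overlaps."""
    rows = []
    for lineno, fields in _parse_lines(path, 4):
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value field") from exc
        rows.append((fields[0], int(fields[1]), int(fields[2]), value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        order = np.argsort(s, kind="mergesort")
        if np.any(s[order][1:] < e[order][:-1]):
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
    return df


def write_bedgraph(df: pd.DataFrame, path: str, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.value:.6g}\n")


def profile_to_bedgraph(profile: BindingProfile, which: str = "smoothed") -> pd.DataFrame:
    """Probe-level profile as bedGraph intervals of one probe spacing each."""
    values = getattr(profile, which)
    spacing = profile.probe_spacing()
    return pd.DataFrame(
        {
            "chrom": profile.chroms,
            "start": profile.positions,
            "end": profile.positions + spacing,
            "value": values,
        }
    )


def bedgraph_to_profile(df: pd.DataFrame, smoothed: bool = True) -> BindingProfile:
    """Interpret bedGraph intervals as probe starts carrying one value each."""
    df = df.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
    values = df["value"].to_numpy(float)
    spacing = None
    if len(df) > 0:
        widths = (df["end"] - df["start"]).to_numpy()
        spacing = int(np.median(widths))
    return BindingProfile(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(np.int64),
        values,
        smoothed=values.copy() if smoothed else None,
        spacing=spacing,
    )


def read_bed(path: str) -> pd.DataFrame:
    """BED3/6/12 -> DataFrame with chrom/start/end and optional name/score/strand."""
    rows = []
    n_cols = 3
    for lineno, fields in _parse_lines(path, 3):
        n_cols = max(n_cols, min(len(fields), 6))
        row = {
            "chrom": fields[0],
            "start": int(fields[1]),
            "end": int(fields[2]),
            "name": fields[3] if len(fields) > 3 else ".",
            "score": float(fields[4]) if len(fields) > 4 and fields[4] != "." else np.nan,
            "strand": fields[5] if len(fields) > 5 else ".",
        }
        if row["strand"] not in ("+", "-", "."):
            raise ValueError(f"{path}:{lineno}: invalid strand {row['strand']!r}")
        rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return df.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


def write_bed(df: pd.DataFrame, path: str, comment: str | None = None) -> None:
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in df.itertuples(index=False):
            name = getattr(row, "name", ".")
            score = getattr(row, "score", np.nan)
            strand = getattr(row, "strand", ".")
            score_s = "." if score is None or (isinstance(score, float) and np.isnan(score)) else f"{score:g}"
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{name}\t{score_s}\t{strand}\n")


def domains_to_bed(domains: DomainSet) -> pd.DataFrame:
    """Domain set as BED6; score = mean window density x 1000."""
    df = domains.domains
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"NAR_{i + 1}" for i in range(len(df))],
            "score": (df["mean_density"] * 1000).round().clip(0, 1000),
            "strand": ".",
        }
    )


def bed_to_domains(df: pd.DataFrame, theta: float = 0.70, window_bp: int = 10_000) -> DomainSet:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "n_probes": np.nan,
            "mean_ratio": np.nan,
            "mean_density": df.get("score", pd.Series(np.nan, index=df.index)) / 1000.0,
        },
        columns=DOMAIN_COLUMNS,
    )
    return DomainSet(out, theta=theta, window_bp=window_bp)


def write_gene_table(genes: pd.DataFrame, bed_path: str, labels_path: str | None = None) -> None:
    """Gene intervals as BED6 (name = gene id) plus a TSV with label columns."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    write_bed(bed, bed_path)
    if labels_path is not None:
        genes[["gene_id", "expressed", "de_status"]].to_csv(labels_path, sep="\t", index=False)


def read_gene_table(bed_path: str, labels_path: str | None = None) -> pd.DataFrame:
    bed = read_bed(bed_path)
    genes = pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )
    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t")
        labels["expressed"] = labels["expressed"].astype(bool)
        genes = genes.merge(labels, on="gene_id", how="left", validate="one_to_one")
        if genes[["expressed", "de_status"]].isna().any().any():
            raise ValueError("incomplete gene labels after merge")
    return genes


def write_stack(stack, directory: str, prefix: str = "nucleus") -> dict[str, str]:
    """One multi-page TIFF per channel; returns the written paths."""
    import tifffile

    os.makedirs(directory, exist_ok=True)
    paths = {}
    for channel in ("dapi", "lamin", "fish"):
        path = os.path.join(directory, f"{prefix}_{channel}.tif")
        tifffile.imwrite(path, getattr(stack, channel))
        paths[channel] = path
    return paths


def read_stack(dapi_path: str, lamin_path: str, fish_path: str, voxel_size: float = 0.1):
    import tifffile

    from .synthetic import NucleusStack

    return NucleusStack(
        dapi=tifffile.imread(dapi_path).astype(np.float32),
        lamin=tifffile.imread(lamin_path).astype(np.float32),
        fish=tifffile.imread(fish_path).astype(np.float32),
        voxel_size=voxel_size,
    )
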