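"""Association tests between called domains and genomic features.

Implements the inside-vs-outside comparisons used to characterise domains:
Fisher's exact test on boolean gene labels (expressed, bound,
down-regulated), Welch's t-test on probe-level marker signal, Wilcoxon
rank-sum on sliding-window gene density, TSS-centred windows for bound
genes, marker co-occurrence, and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .caller import DomainSet
from .intervals import overlap_per_query, points_in_intervals

__all__ = [
    "EnrichmentResult",
    "partition_genes",
    "categorical_enrichment",
    "signal_enrichment",
    "gene_density_track",
    "density_enrichment",
    "tss_window_track",
    "marker_cooccurrence",
    "bh_fdr",
    "adjust_results",
    "format_p",
]

P_FLOOR = 2.2e-16  # display convention for vanishingly small p-values


@dataclass
class EnrichmentResult:
    feature: str
    test: str
    statistic: float
    p_value: float
    inside_summary: float
    outside_summary: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value out of range")

    def as_row(self) -> dict:
        return {
            "feature": self.feature,
            "test": self.test,
            "statistic": self.statistic,
            "inside": self.inside_summary,
            "outside": self.outside_summary,
            "p_value": self.p_value,
            "p_display": format_p(self.p_value),
            "q_value": self.q_value,
        }


def format_p(p: float) -> str:
    """Text rendering with the conventional floor for tiny p-values."""
    return f"<{P_FLOOR:.1e}" if p < P_FLOOR else f"{p:.3g}"


def partition_genes(
    genes: pd.DataFrame,
    nars: DomainSet,
    rule: str = "coverage",
    min_fraction: float = 0.5,
) -> np.ndarray:
    """Boolean mask: which genes count as inside the domain set.

    Rules: 'coverage' (strictly more than ``min_fraction`` of the gene's
    length overlaps domains; the default >50% rule), 'tss' (transcription
    start site falls in a domain), 'any' (any overlap at all).
    """
    if rule not in ("coverage", "tss", "any"):
        raise ValueError("rule must be 'coverage', 'tss' or 'any'")
    inside = np.zeros(len(genes), dtype=bool)
    for chrom, sub in genes.groupby("chrom", sort=False):
        ds, de = nars.intervals(str(chrom))
        idx = sub.index.to_numpy()
        gs = sub["start"].to_numpy(np.int64)
        ge = sub["end"].to_numpy(np.int64)
        if rule == "tss":
            tss = np.where(sub["strand"].to_numpy() == "-", ge, gs)
            inside[genes.index.get_indexer(idx)] = points_in_intervals(tss, ds, de)
        else:
            ov = overlap_per_query(gs, ge, ds, de)
            if rule == "coverage":
                mask = ov > min_fraction * (ge - gs)
            else:
                mask = ov > 0
            inside[genes.index.get_indexer(idx)] = mask
    return inside


def categorical_enrichment(
    label: np.ndarray, inside: np.ndarray, feature: str = "feature"
) -> EnrichmentResult:
    """Fisher's exact test of a boolean gene label against domain membership."""
    label = np.asarray(label, dtype=bool)
    inside = np.asarray(inside, dtype=bool)
    if label.shape != inside.shape:
        raise ValueError("label and membership vectors must align")
    if not inside.any() or inside.all():
        raise ValueError("empty inside/outside partition: cannot form a 2x2 table")
    if not label.any() or label.all():
        raise ValueError("degenerate label margin: all genes share the same label")
    table = np.array(
        [
            [np.sum(label & inside), np.sum(~label & inside)],
            [np.sum(label & ~inside), np.sum(~label & ~inside)],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        feature=feature,
        test="fisher",
        statistic=float(odds),
        p_value=float(p),
        inside_summary=table[0, 0] / table[0].sum(),
        outside_summary=table[1, 0] / table[1].sum(),
    )


def signal_enrichment(
    chroms: np.ndarray,
    positions: np.ndarray,
    values: np.ndarray,
    nars: DomainSet,
    feature: str = "signal",
) -> EnrichmentResult:
    """Welch two-sample t-test of probe-level signal inside vs outside domains."""
    from .tiling import chrom_slices

    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    inside = np.zeros(len(positions), dtype=bool)
    for chrom, sl in chrom_slices(chroms):
        ds, de = nars.intervals(chrom)
        inside[sl] = points_in_intervals(positions[sl], ds, de)
    x, y = values[inside], values[~inside]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 probes on each side")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("constant signal on both sides: t statistic undefined")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return EnrichmentResult(
        feature=feature,
        test="welch-t",
        statistic=float(t),
        p_value=float(p),
        inside_summary=float(x.mean()),
        outside_summary=float(y.mean()),
    )


def gene_density_track(
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 20_000,
    offset_bp: int = 1_000,
) -> pd.DataFrame:
    """Count of genes overlapping each sliding window (columns chrom/start/end/count).

    Windows tile each chromosome at ``offset_bp`` steps; a gene counts when
    its interval overlaps the window at all.
    """
    if window_bp <= offset_bp:
        raise ValueError("window_bp must exceed offset_bp")
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, max(length - window_bp, 0) + 1, offset_bp, dtype=np.int64)
        sub = genes[genes["chrom"] == chrom]
        gs = np.sort(sub["start"].to_numpy(np.int64))
        ge = np.sort(sub["end"].to_numpy(np.int64))
        count = np.searchsorted(gs, starts + window_bp, side="left") - np.searchsorted(
            ge, starts, side="right"
        )
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + window_bp, "count": count}
            )
        )
    return pd.concat(frames, ignore_index=True)


def density_enrichment(track: pd.DataFrame, nars: DomainSet, feature: str = "gene_density") -> EnrichmentResult:
    """Wilcoxon rank-sum test of window gene counts inside vs outside domains.

    A window counts as inside when its midpoint falls in a domain.
    """
    inside = np.zeros(len(track), dtype=bool)
    for chrom, sub in track.groupby("chrom", sort=False):
        ds, de = nars.intervals(str(chrom))
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy(np.int64)
        inside[track.index.get_indexer(sub.index)] = points_in_intervals(mid, ds, de)
    x = track["count"].to_numpy(float)[inside]
    y = track["count"].to_numpy(float)[~inside]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty inside/outside window partition")
    stat, p = stats.ranksums(x, y)
    return EnrichmentResult(
        feature=feature,
        test="wilcoxon",
        statistic=float(stat),
        p_value=float(p),
        inside_summary=float(np.median(x)),
        outside_summary=float(np.median(y)),
    )


def tss_window_track(
    genes: pd.DataFrame, width_bp: int = 1_000, chrom_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Fixed-width windows centred on each gene's transcription start site.

    TSS is the interval start for '+' strand genes and the end for '-'
    strand; windows are clipped at 0 and, when lengths are given, at the
    chromosome end.
    """
    if len(genes) == 0:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
    strands = genes["strand"].to_numpy()
    if np.any(~np.isin(strands, ["+", "-"])):
        raise ValueError("all genes must have '+' or '-' strand for TSS windows")
    half = width_bp // 2
    tss = np.where(strands == "-", genes["end"].to_numpy(np.int64), genes["start"].to_numpy(np.int64))
    start = np.maximum(tss - half, 0)
    end = tss + half
    if chrom_lengths is not None:
        limits = genes["chrom"].map(chrom_lengths).to_numpy(np.int64)
        end = np.minimum(end, limits)
    return pd.DataFrame(
        {"gene_id": genes["gene_id"].to_numpy(), "chrom": genes["chrom"].to_numpy(), "start": start, "end": end}
    )


def marker_cooccurrence(
    values_a: np.ndarray,
    values_b: np.ndarray,
    cutoff_a: float,
    cutoff_b: float,
    feature: str = "cooccurrence",
) -> dict:
    """Per-probe significance masks for two markers and their 2x2 exclusivity test.

    Probes at or above a marker's cutoff are significant for it. Returns the
    fraction significant for both plus Fisher's exact test of the 2x2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("marker tracks must share the same probe grid")
    sig_a = a >= cutoff_a
    sig_b = b >= cutoff_b
    both = sig_a & sig_b
    table = np.array(
        [
            [np.sum(sig_a & sig_b), np.sum(sig_a & ~sig_b)],
            [np.sum(~sig_a & sig_b), np.sum(~sig_a & ~sig_b)],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "feature": feature,
        "fraction_a": float(sig_a.mean()),
        "fraction_b": float(sig_b.mean()),
        "fraction_both": float(both.mean()),
        "odds_ratio": float(odds),
        "p_value": float(p),
    }


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def adjust_results(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Fill q-values across a batch of enrichment results (BH)."""
    q = bh_fdr(np.array([r.p_value for r in results]))
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results
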