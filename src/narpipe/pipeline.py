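"""End-to-end synthetic run tying the stages together.

Generates a planted-domain genome, processes the tiling signal, calls
domains, runs the enrichment battery, simulates nuclei for the
localisation references, and writes a deterministic report bundle stamped
with the configuration hash.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import enrichment as enr
from .caller import call_domains, domain_overlap, occupancy_stats, positive_probe_density
from .config import RunConfig
from .io import domains_to_bed, profile_to_bedgraph, write_bed, write_bedgraph, write_gene_table
from .localisation import classify_loci, simulate_reference
from .synthetic import GenomeSpec, PlantedDomain, generate_binding_profile, generate_gene_table, generate_probe_layout
from .tiling import smooth

log = logging.getLogger("narpipe")

__all__ = ["plant_domains", "pipeline_run"]


def plant_domains(
    genome: GenomeSpec,
    p_in: float,
    p_out: float,
    domain_bp: int = 50_000,
    block_bp: int = 200_000,
    seed: int = 0,
) -> list[PlantedDomain]:
    """One fixed-length domain per block of each chromosome, at a random offset.

    With the defaults this covers 25% of the genome in 50 kb domains.
    """
    rng = np.random.default_rng(seed)
    domains = []
    for name, length in genome.chromosomes:
        for block_start in range(0, length - block_bp + 1, block_bp):
            offset = int(rng.integers(0, block_bp - domain_bp + 1))
            start = block_start + offset
            domains.append(PlantedDomain(name, start, start + domain_bp, p_in=p_in, p_out=p_out))
    return domains


def _truth_domain_set(domains, theta, window_bp):
    from .caller import DOMAIN_COLUMNS, DomainSet

    df = pd.DataFrame(
        [
            {"chrom": d.chromosome, "start": d.start, "end": d.end, "n_probes": np.nan,
             "mean_ratio": np.nan, "mean_density": np.nan}
            for d in sorted(domains, key=lambda d: (d.chromosome, d.start))
        ],
        columns=DOMAIN_COLUMNS,
    )
    return DomainSet(df, theta=theta, window_bp=window_bp)


def pipeline_run(config: RunConfig, outdir: str) -> dict:
    """Run the full synthetic chain and write the report bundle to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    t0 = time.perf_counter()
    chash = config.config_hash()
    stamp = f"narpipe config_hash={chash}"
    rng = np.random.default_rng(config.seed)

    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        log.info("stage %-14s t=%.1fs", name, time.perf_counter() - t0)

    try:
        stage("simulate-chip")
        genome = GenomeSpec(
            chromosomes=[(f"chr{i + 1}", config.chromosome_bp) for i in range(config.n_chromosomes)],
            probe_spacing=config.probe_spacing,
            seed=config.seed,
        )
        layout = generate_probe_layout(genome)
        planted = plant_domains(genome, config.p_in, config.p_out, seed=int(rng.integers(2**31)))
        profile = generate_binding_profile(
            layout, planted, p_out=config.p_out, seed=int(rng.integers(2**31)),
            spacing=config.probe_spacing, lengths=genome.lengths,
        )
        profile = smooth(profile, config.smooth_bp)

        stage("call-nars")
        density = positive_probe_density(profile, config.window_bp)
        nars = call_domains(density, config.theta, config.max_gap_probes, config.extent)
        truth = _truth_domain_set(planted, config.theta, config.window_bp)
        recovery = domain_overlap(nars, truth)
        occupancy = occupancy_stats(nars, genome.lengths)

        write_bedgraph(profile_to_bedgraph(profile, "smoothed"), os.path.join(outdir, "smoothed.bedgraph"), stamp)
        write_bed(domains_to_bed(nars), os.path.join(outdir, "nars.bed"), stamp)
        occupancy.to_csv(os.path.join(outdir, "occupancy.tsv"), sep="\t", index=False)

        stage("enrich")
        genes = generate_gene_table(
            layout, planted, n_genes=config.n_genes,
            p_expr_in=config.p_expr_in, p_expr_out=config.p_expr_out,
            seed=int(rng.integers(2**31)),
        )
        write_gene_table(genes, os.path.join(outdir, "genes.bed"), os.path.join(outdir, "gene_labels.tsv"))
        inside = enr.partition_genes(genes, nars, config.overlap_rule, config.min_overlap_fraction)
        results = [
            enr.categorical_enrichment(genes["expressed"].to_numpy(), inside, "expressed_genes"),
            enr.categorical_enrichment((genes["de_status"] == "down").to_numpy(), inside, "down_regulated_genes"),
            enr.signal_enrichment(profile.chroms, profile.positions, profile.smoothed, nars, "binding_signal"),
            enr.density_enrichment(
                enr.gene_density_track(genes, genome.lengths, config.density_window_bp, config.density_offset_bp),
                nars,
            ),
        ]
        enr.adjust_results(results)
        pd.DataFrame([r.as_row() for r in results]).to_csv(
            os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False
        )

        stage("simulate-nuclei")
        seeds = rng.integers(2**31, size=4)
        per_ctrl = simulate_reference(
            "peripheral", config.signal_extent, config.n_nuclei, int(seeds[0]),
            config.nucleus_radius, config.noise_sd, locus_id="L105-like",
        )
        int_ctrl = simulate_reference(
            "interior", config.signal_extent, config.n_nuclei, int(seeds[1]),
            config.nucleus_radius, config.noise_sd, locus_id="N2-like",
        )
        targets = [
            simulate_reference("peripheral", config.signal_extent, config.n_nuclei, int(seeds[2]),
                               config.nucleus_radius, config.noise_sd, locus_id="target-peripheral"),
            simulate_reference("interior", config.signal_extent, config.n_nuclei, int(seeds[3]),
                               config.nucleus_radius, config.noise_sd, locus_id="target-interior"),
        ]

        stage("classify-loci")
        calls = classify_loci(targets, per_ctrl, int_ctrl, config.alpha)
        loc_df = pd.DataFrame(
            [
                {
                    "locus": c.locus_id,
                    "n_nuclei": t.n,
                    "median_distance": t.median,
                    "p_vs_peripheral": c.p_vs_peripheral,
                    "p_vs_interior": c.p_vs_interior,
                    "q_vs_peripheral": c.q_vs_peripheral,
                    "q_vs_interior": c.q_vs_interior,
                    "call": c.call,
                }
                for t, c in zip(targets, calls)
            ]
        )
        loc_df.to_csv(os.path.join(outdir, "localisation.tsv"), sep="\t", index=False)
    except Exception as exc:  # re-raise with stage attribution
        raise RuntimeError(f"pipeline failed in stage {current_stage!r}: {exc}") from exc

    config.to_toml(os.path.join(outdir, "config.toml"))
    summary = {
        "config_hash": chash,
        "n_nars": len(nars),
        "nar_bp": nars.total_bp,
        "recovery_jaccard": recovery["jaccard"],
        "occupancy_pct_genome": float(
            occupancy.loc[occupancy["group"] == "genome", "occupancy_pct"].iloc[0]
        ),
        "n_genes": len(genes),
        "enrichment": [r.as_row() for r in results],
        "localisation_calls": {c.locus_id: c.call for c in calls},
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    stage("done")
    return summary
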