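# narpipe

Analysis toolkit for nucleoporin-associated chromatin regions (NARs) and
their sub-nuclear localisation, built around three stages:

1. **Tiling signal → domain calls.** Probe-level IP/input intensities are
   quantile-normalized, replicate-averaged, converted to log2(ChIP/input)
   ratios, and smoothed in a 500 bp window. A 10 kb window slides along
   each chromosome, centred on each probe start, scoring the fraction of
   probes with positive smoothed ratio; maximal runs of probes whose
   window density exceeds 70% become domains. Includes a label-shuffle
   randomization null, a two-stage seed-and-extend alternative caller,
   bp-overlap/Jaccard reports, and per-chromosome-group occupancy
   summaries.
2. **Enrichment statistics.** Fisher's exact test for boolean gene labels
   (expressed, bound, down-regulated) inside vs outside domains (default
   membership rule: >50% of gene length covered), Welch's t-test for
   probe-level marker signal, Wilcoxon rank-sum for sliding-window gene
   density, TSS-centred windows, marker co-occurrence, and
   Benjamini–Hochberg FDR adjustment.
3. **3D FISH localisation.** Nuclei are segmented from DAPI stacks by Otsu
   thresholding (largest component, slice-wise hole filling), checked
   against a single-voxel lamin rim, and converted to a Euclidean
   distance-to-boundary map. FISH voxels inside the mask are thresholded
   and their distances summarised per nucleus, normalized by the nuclear
   radius (0 = boundary, 1 = centroid). Loci are classified
   peripheral/non-peripheral by Wilcoxon tests against peripheral and
   interior control distributions under batch-wide FDR, and
   depletion-induced relocalisation is tested with a 30%-of-radius
   peripheral threshold.

A synthetic-data module generates all inputs with the statistical
structure the pipeline assumes: evenly spaced probe layouts (35 bp),
binding profiles with planted high-density domains, gene tables whose
expression labels depend on domain membership, and voxelized
three-channel nucleus stacks (DAPI sphere, lamin shell, spherical FISH
signal), so every stage is testable without external data.

## CLI

```sh
narpipe simulate-chip --chrom-bp 2000000 --p-in 0.9 --p-out 0.3 --seed 1 --out probes.bedgraph
narpipe call-nars --profile probes.bedgraph --smooth-bp 500 --window 10000 --theta 0.70 --out nars.bed
narpipe simulate-nuclei --mode peripheral --radius 25 --seed 2 --outdir nuclei/
narpipe measure-fish --dapi d.tif --lamin l.tif --fish f.tif --out fish.tsv
narpipe classify-loci --targets targets.tsv --peripheral-control per.tsv \
    --interior-control int.tsv --out calls.tsv
narpipe run-all --seed 1 --outdir run/        # synthetic end-to-end bundle
```

`run-all` writes a deterministic report bundle (NAR BED, occupancy and
enrichment TSVs, localisation calls, smoothed bedGraph, resolved TOML
config, JSON summary), each stamped with the configuration hash.

## Layout

- `src/narpipe/synthetic.py` — seed-deterministic generators (probes, profiles, genes, nuclei)
- `src/narpipe/tiling.py` — quantile normalization, ratio profiles, smoothing
- `src/narpipe/caller.py` — density track, domain calling, shuffle null, overlap/occupancy
- `src/narpipe/enrichment.py` — Fisher/t/Wilcoxon enrichment, TSS windows, BH-FDR
- `src/narpipe/imaging.py` — segmentation, rim refinement, distance maps, FISH distances
- `src/narpipe/localisation.py` — simulated references, locus classification, depletion tests
- `src/narpipe/io.py`, `config.py`, `cli.py`, `pipeline.py` — formats, configuration, CLI, end-to-end run
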