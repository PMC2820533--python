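"""Run configuration: one flat record of every stage parameter.

Defaults match the published analysis (10 kb density window, 70% threshold,
500 bp smoothing, >50% gene-overlap rule, alpha 0.05, 30% peripheral
threshold). Round-trips losslessly through TOML and hashes canonically so
outputs can be stamped with the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass


@dataclass
class RunConfig:
    # tiling signal
    smooth_bp: int = 500
    # domain calling
    window_bp: int = 10_000
    theta: float = 0.70
    extent: str = "probes"
    max_gap_probes: int = 0
    seed_theta: float = 0.80
    extend_theta: float = 0.60
    # enrichment
    overlap_rule: str = "coverage"
    min_overlap_fraction: float = 0.5
    density_window_bp: int = 20_000
    density_offset_bp: int = 1_000
    tss_window_bp: int = 1_000
    alpha: float = 0.05
    # imaging / localisation
    nucleus_radius: int = 25
    signal_extent: float = 0.30
    noise_sd: float = 5.0
    rim_tolerance: float = 2.0
    peripheral_threshold: float = 0.30
    n_nuclei: int = 30
    # synthetic genome
    probe_spacing: int = 35
    chromosome_bp: int = 2_000_000
    n_chromosomes: int = 2
    p_in: float = 0.90
    p_out: float = 0.30
    n_genes: int = 800
    p_expr_in: float = 0.63
    p_expr_out: float = 0.40
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_toml(self, path: str) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                if isinstance(value, bool):
                    fh.write(f"{key} = {'true' if value else 'false'}\n")
                elif isinstance(value, str):
                    fh.write(f'{key} = "{value}"\n')
                else:
                    fh.write(f"{key} = {value}\n")

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
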