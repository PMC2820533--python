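"""Shared constructors for hand-built fixtures."""

import pandas as pd

from narpipe.caller import DomainSet


def make_domains(records, theta=0.7, window=10_000):
    df = pd.DataFrame(records, columns=["chrom", "start", "end"])
    df["n_probes"] = 0
    df["mean_ratio"] = 0.0
    df["mean_density"] = 0.9
    return DomainSet(df, theta=theta, window_bp=window)


def gene_df(records):
    return pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand", "expressed", "de_status"]
    )
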