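import numpy as np
import pytest

import narpipe as npk
from narpipe.pipeline import _truth_domain_set, plant_domains


@pytest.fixture(scope="session")
def genome():
    return npk.GenomeSpec([("chr1", 2_000_000), ("chr2", 2_000_000)], probe_spacing=35)


@pytest.fixture(scope="session")
def layout(genome):
    return npk.generate_probe_layout(genome)


@pytest.fixture(scope="session")
def planted(genome):
    return plant_domains(genome, p_in=0.9, p_out=0.3, seed=7)


@pytest.fixture(scope="session")
def truth_set(planted):
    return _truth_domain_set(planted, theta=0.70, window_bp=10_000)


@pytest.fixture(scope="session")
def profile(layout, planted, genome):
    prof = npk.generate_binding_profile(
        layout, planted, p_out=0.3, seed=11, spacing=35, lengths=genome.lengths
    )
    return npk.smooth(prof, 500)


@pytest.fixture(scope="session")
def density(profile):
    return npk.positive_probe_density(profile, 10_000)


@pytest.fixture(scope="session")
def nars(density):
    return npk.call_domains(density, 0.70)


@pytest.fixture(scope="session")
def genes(layout, planted):
    return npk.generate_gene_table(layout, planted, n_genes=600, seed=5)


@pytest.fixture(scope="session")
def peripheral_control():
    return npk.simulate_reference("peripheral", n=60, seed=900, radius=16)


@pytest.fixture(scope="session")
def interior_control():
    return npk.simulate_reference("interior", n=60, seed=901, radius=16)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
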