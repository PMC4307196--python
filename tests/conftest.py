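import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hyperbin as hb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_community():
    """A well-separated 2-phyla x 2-orders community, 30 reads of 400 nt
    per taxon."""
    spec = hb.CommunitySpec(
        n_phyla=2, orders_per_phylum=2, reads_per_taxon=30,
        read_length=400, separation=5.0, seed=7,
    )
    taxa = hb.sample_taxa(spec)
    records, lineages = hb.generate_reads(taxa, spec)
    return spec, taxa, records, lineages


@pytest.fixture(scope="session")
def small_model(small_community):
    """A trained and labeled model on a small 2-ring lattice."""
    _, _, records, lineages = small_community
    return hb.build_model(
        records, lineages, k=4, s=8, r=2,
        training=hb.TrainingConfig(seed=7),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
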