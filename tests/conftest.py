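import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cohortref import Catalog, normalize_genome, sample_profile, simulate_genomes

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20231014)


@pytest.fixture(scope="session")
def tiny_catalog():
    """Three random 2 kb genomes; enough for exact-match alignment tests."""
    _, catalog = simulate_genomes(3, 2000, seed=42)
    return catalog


@pytest.fixture(scope="session")
def small_community():
    """A 6-genome community with a skewed profile (session-scoped for speed)."""
    _, catalog = simulate_genomes(6, 5000, seed=7)
    profile = sample_profile(6, sigma=1.5, seed=7)
    return catalog, profile


def make_catalog(seqs: dict[str, str]) -> Catalog:
    return Catalog([normalize_genome([s], gid) for gid, s in seqs.items()])
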