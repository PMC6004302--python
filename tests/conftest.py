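import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import paleozone as pz

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return pz.frame_lake_registry()


@pytest.fixture(scope="session")
def lake_counts(registry):
    """The packaged 30 x 32 relative-abundance table."""
    return pz.frame_lake_assemblage(registry=registry)


@pytest.fixture(scope="session")
def lake_rel(lake_counts):
    return pz.to_relative(lake_counts)


@pytest.fixture(scope="session")
def lake_bc_sqrt(lake_rel):
    """Bray-Curtis of square-root transformed relative abundances."""
    return pz.bray_curtis(pz.sqrt_transform(lake_rel))


@pytest.fixture(scope="session")
def lake_bc_raw(lake_rel):
    """Bray-Curtis of untransformed relative abundances (zonation matrix)."""
    return pz.bray_curtis(lake_rel, expect_transformed=False)


@pytest.fixture(scope="session")
def lake_counts_n150(lake_counts):
    """Counts reconstructed from the printed abundances at N = 150."""
    vals = np.round(lake_counts.values * 150)
    return lake_counts.replace(values=vals, mode="counts", totals=None)


@pytest.fixture(scope="session")
def printed_indices():
    return pz.frame_lake_printed_indices()


@pytest.fixture(scope="session")
def lake_zones(lake_bc_raw):
    """Three-zone CONISS assignment of the packaged core (deep zone = 1)."""
    return pz.coniss(lake_bc_raw).zones(3)


def random_dissimilarity(rng, n):
    """Helper: a random symmetric dissimilarity matrix with zero diagonal."""
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return pz.ResemblanceMatrix([f"s{i}" for i in range(n)], m, coefficient="random")
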