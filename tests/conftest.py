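import numpy as np
import pytest

from rohcompare import GenotypeMatrix


def make_matrix(calls, positions=None, chromosomes=None, channel="array",
                individuals=None):
    """Build a small GenotypeMatrix from an (n_ind, n_sites) call grid."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10_000
    if chromosomes is None:
        chromosomes = np.ones(n_sites, dtype=np.int16)
    if individuals is None:
        individuals = [f"s{i}" for i in range(n_ind)]
    return GenotypeMatrix(
        chromosomes=np.asarray(chromosomes, dtype=np.int16),
        positions=np.asarray(positions, dtype=np.int64),
        site_ids=[f"rs{j}" for j in range(n_sites)],
        ref_alleles=["A"] * n_sites,
        alt_alleles=["G"] * n_sites,
        individuals=individuals,
        calls=calls,
        channel=channel,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
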