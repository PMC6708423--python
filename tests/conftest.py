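import numpy as np
import pytest

from spruce_demog import DemographicModel, GenotypeMatrix, Population, Site


def make_matrix(calls, samples=None, chrom="1", spacing=100):
    """GenotypeMatrix from a (samples × sites) list-of-lists of dosages."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    sites = [Site(chrom, 1 + spacing * j, "A", "T") for j in range(n_sites)]
    return GenotypeMatrix(samples, sites, calls)


@pytest.fixture
def tiny_matrix():
    # 3 samples × 4 sites with one missing call
    return make_matrix(
        [
            [0, 1, 2, 0],
            [1, 1, 0, -1],
            [2, 0, 0, 1],
        ]
    )


@pytest.fixture
def constant_model():
    """Single panmictic population of diploid size 1000."""
    return DemographicModel([Population("A", 1000.0)], events=[], migration={})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
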