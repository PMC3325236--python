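import numpy as np
import pytest

from bxdnet.datatypes import MarkerMap, ProbeLevelArray
from bxdnet.simulate import make_dataset, make_genotypes


@pytest.fixture(scope="session")
def small_map():
    return MarkerMap.regular(n_chromosomes=2, markers_per_chr=10,
                             spacing_mb=10.0)


@pytest.fixture(scope="session")
def panel(small_map):
    return make_genotypes(20, small_map, 0.25, seed=42)


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic dataset, shared read-only across tests."""
    return make_dataset(1234, n_probe_sets=800)


def null_chip_pair(n_probe_sets: int, seed: int, probes: int = 11,
                   probe_noise_sd: float = 0.1):
    """Two arrays with identical true expression and independent probe noise."""
    rng = np.random.default_rng(seed)
    ids = [f"ps{i:05d}" for i in range(n_probe_sets)]
    true = rng.uniform(5, 12, size=n_probe_sets)
    affinity = np.exp(rng.normal(0, 0.5, size=(n_probe_sets, probes)))
    def chip():
        noise = np.exp(rng.normal(0, probe_noise_sd,
                                  size=(n_probe_sets, probes)))
        return ProbeLevelArray(ids, (2.0 ** true)[:, None] * affinity * noise)
    return chip(), chip()
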