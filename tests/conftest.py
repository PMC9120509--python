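import numpy as np
import pandas as pd
import pytest

from holoselect.genolik import GenotypeLikelihoods
from holoselect.simulate import SimConfig, simulate_all, simulate_population


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_sites=300, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One full synthetic dataset shared by read-only tests."""
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def small_truth(small_dataset):
    return small_dataset["truth"]


def make_gl(triplets, sites=None, samples=None) -> GenotypeLikelihoods:
    """GenotypeLikelihoods from an explicit (sites, samples, 3) nested list."""
    gl = np.asarray(triplets, dtype=float)
    n_sites, n_samples = gl.shape[:2]
    if sites is None:
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * n_sites,
                "pos": np.arange(1, n_sites + 1) * 100,
                "ref": ["A"] * n_sites,
                "alt": ["G"] * n_sites,
            }
        )
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeLikelihoods(sites=sites, samples=samples, gl=gl)
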