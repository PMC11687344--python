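import numpy as np
import pytest

from metaoccu.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic study reused by read-only tests (8 species,
    6 sites, 3 years, 6 surveys)."""
    return generate_dataset(GeneratorConfig(n_species=8, n_sites=6,
                                            n_restored=3, seed=3))


@pytest.fixture(scope="session")
def medium_dataset():
    """A medium synthetic study for likelihood-level checks."""
    return generate_dataset(GeneratorConfig(n_species=15, n_sites=8,
                                            n_restored=4, seed=17))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
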