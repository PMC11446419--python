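import numpy as np
import pytest

from phenospec import SyntheticConfig, generate_cohort, make_reference_spectrum


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort (8 cultivars x 3 cuts x 2 reps = 48 samples, 2 nm grid)."""
    return SyntheticConfig(n_cultivars=8, n_replicates=2, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def reference(small_config):
    return make_reference_spectrum(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
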