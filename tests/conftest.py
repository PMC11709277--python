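import numpy as np
import pytest

from reccp import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240509)


@pytest.fixture(scope="session")
def small_cohort():
    """A quantization-free cohort where recCP equals the hidden truth."""
    cfg = CohortConfig(n=200, seed=7, quantize=False)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the study's size with clinical quantization on."""
    cfg = CohortConfig(n=509, seed=11)
    return generate_cohort(cfg)
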