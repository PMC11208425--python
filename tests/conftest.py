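import numpy as np
import pytest

from muscleidp.phantom import CohortSimSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom with the default geometry and noise."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(hu_noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSimSpec(n_subjects=400, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
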