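import numpy as np
import pytest

from gliomics.phantom import (
    CohortSpec,
    PhantomSpec,
    fixture_masks,
    generate_cohort,
    generate_phantom_subject,
)


@pytest.fixture(scope="session")
def phantom():
    """Default 64^3 phantom: (volume, label_map, brain_mask, region_counts)."""
    return generate_phantom_subject(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom_subject(PhantomSpec(noise_sigma=0.0, seed=1))


@pytest.fixture(scope="session")
def masks():
    """Named binary masks with known Euler characteristic."""
    return fixture_masks()


@pytest.fixture(scope="session")
def cohort():
    """163-subject synthetic cohort with 5 planted hazard features."""
    return generate_cohort(CohortSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
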