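import numpy as np
import pytest

from cidnet import SimulationConfig, define_cohorts, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (seed 1), shared read-only."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_cohorts(default_cohort):
    _, clinical, _ = default_cohort
    return define_cohorts(clinical)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
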