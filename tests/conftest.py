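import numpy as np
import pytest

from qgcn import CohortSpec, NoiseSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Low-noise 20-sample cohort with its ground truth (session-shared)."""
    design = CohortSpec(n_samples=20)
    noise = NoiseSpec()
    records, truth = simulate_cohort(design, noise, seed=7)
    return records, truth
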