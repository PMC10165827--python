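import numpy as np
import pytest

from parosal import DoseVolumeHistogram, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """50-patient synthetic cohort used by I/O and bookkeeping tests."""
    return generate_cohort(GeneratorConfig(n_patients=50, seed=11))


@pytest.fixture(scope="session")
def medium_cohort():
    """500-patient synthetic cohort shared by the model-fitting tests."""
    return generate_cohort(GeneratorConfig(n_patients=500, seed=7))


@pytest.fixture
def two_bin_dvh():
    """60% of the organ at 20 Gy, 40% at 60 Gy."""
    return DoseVolumeHistogram(np.array([0.0, 20.0, 60.0]), np.array([1.0, 0.4, 0.0]))


def random_dvh(rng: np.random.Generator, max_edges: int = 12) -> DoseVolumeHistogram:
    """Random monotone step function satisfying the DVH invariants."""
    k = rng.integers(2, max_edges + 1)
    edges = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 70.0, size=k - 1))])
    vols = np.concatenate([[1.0], np.sort(rng.uniform(0.0, 1.0, size=k - 1))[::-1]])
    return DoseVolumeHistogram(edges, vols)
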