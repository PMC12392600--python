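import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pedpca import Pedigree, random_pedigree

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def trio() -> Pedigree:
    """Two founders and their offspring."""
    return Pedigree.from_indices([0, 0, 1], [0, 0, 2])


@pytest.fixture
def fullsib() -> Pedigree:
    """Full-sib mating: 3 and 4 are full sibs (1 x 2), 5 = 3 x 4."""
    return Pedigree.from_indices([0, 0, 1, 1, 3], [0, 0, 2, 2, 4])


@pytest.fixture
def parent_offspring() -> Pedigree:
    """Parent-offspring mating: 3 = 1 x 2, then 4 = 1 x 3."""
    return Pedigree.from_indices([0, 0, 1, 1], [0, 0, 2, 3])


@pytest.fixture
def founders_only() -> Pedigree:
    return Pedigree.from_indices([0] * 20, [0] * 20)


def small_pedigrees(count: int = 20, nmax: int = 120):
    """Deterministic battery of random pedigrees with mixed unknown parents."""
    rng = np.random.default_rng(20_240_101)
    for i in range(count):
        n = int(rng.integers(5, nmax))
        yield random_pedigree(n, seed=i, p_missing=float(rng.uniform(0.0, 0.5)))
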