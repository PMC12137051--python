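import numpy as np
import pytest

from virunet.core import MetapopState
from virunet.landscapes import (
    LandscapeGraph,
    OcnAnnealConfig,
    generate_ocn,
    generate_rgg,
)

#: a fast annealing configuration for tests that need many OCNs
FAST_OCN = OcnAnnealConfig(n_iterations=1500)


@pytest.fixture(scope="session")
def rgg100() -> LandscapeGraph:
    return generate_rgg(100, 0.15, seed=11)


@pytest.fixture(scope="session")
def ocn100() -> LandscapeGraph:
    return generate_ocn(FAST_OCN, seed=11)


@pytest.fixture
def two_patch() -> LandscapeGraph:
    return LandscapeGraph(2, ((0, 1),), kind="custom")


def random_state(rng: np.random.Generator, n_patches: int = 20) -> MetapopState:
    """A random but structurally valid metapopulation state."""
    S = rng.integers(0, 50, size=n_patches).astype(np.int64)
    m = int(rng.integers(1, 200))
    return MetapopState(
        S=S,
        inf_patch=rng.integers(0, n_patches, size=m).astype(np.int64),
        inf_v=rng.uniform(0.05, 1.0, size=m),
        inf_allele=rng.integers(0, 30, size=m).astype(np.int64),
        t=0,
        next_allele=30,
    )
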