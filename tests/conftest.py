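from __future__ import annotations

import numpy as np
import pytest

from findlv import Dataset4D, Volume3D
from findlv.phantom import PhantomParams, generate_phantom


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140)


@pytest.fixture
def random_dataset(rng) -> Dataset4D:
    """Small random 4D dataset with values spanning the HU window."""
    stack = rng.uniform(-100, 400, size=(5, 6, 6, 6))
    return Dataset4D([Volume3D(stack[p]) for p in range(5)])


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (seed 7) shared across tests that only read it."""
    params = PhantomParams(seed=7)
    dataset, truth = generate_phantom(params)
    return params, dataset, truth
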