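import numpy as np
import pytest

import gba


@pytest.fixture
def example():
    return gba.build_example_model()


@pytest.fixture
def example_model(example):
    return example[0]


@pytest.fixture
def example_conditions(example):
    return example[1]


@pytest.fixture
def minimal():
    """A fixed-parameter 2-reaction self-replicator."""
    return gba.minimal_model(kcat_t=100.0, K_t=0.5, kcat_r=20.0, K_r=5.0,
                             rho=300.0, a=10.0)


@pytest.fixture
def fast_options():
    """Fewer multistarts: plenty for the 1-2 D problems in the suite."""
    return gba.SolverOptions(n_starts=4, seed=42)


def random_minimal(seed: int):
    """Seeded random parameters for the minimal self-replicator."""
    rng = np.random.default_rng(seed)
    kcat_t, kcat_r = rng.uniform(1.0, 100.0, 2)
    K_t, K_r = rng.uniform(0.1, 10.0, 2)
    rho = rng.uniform(200.0, 400.0)
    a = rng.uniform(0.1, 10.0)
    params = dict(kcat_t=kcat_t, K_t=K_t, kcat_r=kcat_r, K_r=K_r,
                  rho=rho, a=a)
    model, conditions = gba.minimal_model(**params)
    return model, conditions, params
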