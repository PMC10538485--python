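import numpy as np
import pytest

from gammasmc import ModelParams, build_flow_field, build_skip_cache

THETA = 0.00075
RHO = 0.0006


@pytest.fixture(scope="session")
def grid():
    """Flow field at the study rates."""
    return build_flow_field(RHO)


@pytest.fixture(scope="session")
def grid0():
    """Flow field without recombination (identity map)."""
    return build_flow_field(0.0)


@pytest.fixture(scope="session")
def cache(grid):
    """Default (exact) skip cache, shortened for test runtime."""
    return build_skip_cache(grid, THETA, max_len=2000)


@pytest.fixture(scope="session")
def cache_iterated(grid):
    """Iterated-projection cache in float64 (bit-exact vs sequential stepping)."""
    return build_skip_cache(grid, THETA, max_len=300, dtype=np.float64,
                            method="iterated")


@pytest.fixture(scope="session")
def cache0(grid0):
    return build_skip_cache(grid0, THETA, max_len=500)


@pytest.fixture(scope="session")
def params():
    return ModelParams(theta=THETA, rho=RHO, Ne=15_000)


@pytest.fixture(scope="session")
def params0():
    return ModelParams(theta=THETA, rho=0.0, Ne=15_000)
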