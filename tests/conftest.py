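import numpy as np
import pandas as pd
import pytest

from racbrt import (
    BRTConfig,
    build_weights,
    default_response_spec,
    full_coverage_design,
    generate_grid,
    simulate_covariates,
    simulate_presence,
)


@pytest.fixture(scope="session")
def grid12():
    """Small dense study grid used by the mid-weight pipeline tests."""
    return generate_grid(12, 12, 5.0)


@pytest.fixture(scope="session")
def weights12(grid12):
    return build_weights(grid12)


@pytest.fixture(scope="session")
def survey12(grid12):
    return full_coverage_design(grid12)


@pytest.fixture(scope="session")
def cells12(grid12, survey12):
    """One seeded synthetic world on the 12x12 grid (covariates + presence)."""
    cov = simulate_covariates(grid12, seed=11)
    pres, info = simulate_presence(grid12, cov, default_response_spec(), survey12, seed=12)
    return cov.join(pres)


@pytest.fixture(scope="session")
def small_brt_config():
    """Cheap booster settings for unit tests."""
    return BRTConfig(lr=0.05, tc=2, n_folds=5, max_trees=150, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_binary_response(X: pd.DataFrame, column: str, rng) -> np.ndarray:
    """y = 1{x > median} with 10% label flips."""
    y = (X[column] > X[column].median()).astype(int).to_numpy()
    flip = rng.random(len(y)) < 0.1
    return np.where(flip, 1 - y, y)
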