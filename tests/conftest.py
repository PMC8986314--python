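import numpy as np
import pytest

from dieltrsf import ModelData


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def random_model_data(rng, n_events=8, n_covariates=2, n_cities=2) -> ModelData:
    """A small, valid random instance for density-function tests."""
    alpha = rng.uniform(0.5, 12.0, (n_events, 5))
    return ModelData(
        X=rng.normal(0, 1, (n_events, n_covariates)),
        y=rng.integers(0, 5, n_events),
        log_alpha=np.log(alpha),
        city=rng.integers(0, n_cities, n_events),
        n_cities=n_cities,
    )


@pytest.fixture
def small_data(rng):
    return random_model_data(rng)
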