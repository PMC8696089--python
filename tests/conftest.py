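import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import codaratio as cr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_x(rng):
    """20 samples x 6 features, strictly positive."""
    return cr.CompositionMatrix(rng.uniform(0.2, 8.0, (20, 6)))


@pytest.fixture(scope="session")
def planted_dataset():
    """Moderate planted-balance dataset shared across fit tests."""
    cfg = cr.SimulationConfig(
        n=400, p=30,
        planted=[cr.PlantedRatio(cr.BalancePartition((0, 1), (2,)), 4.0)],
        seed=42,
    )
    return cr.simulate(cfg)


@pytest.fixture(scope="session")
def planted_model(planted_dataset):
    d = planted_dataset
    return cr.fit_ensemble(d.x, d.y, cfg=cr.RelaxationFitConfig(seed=42))


@pytest.fixture(scope="session")
def noise_dataset():
    cfg = cr.SimulationConfig(n=300, p=20, planted=[], seed=7)
    return cr.simulate(cfg)
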