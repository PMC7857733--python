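import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import syndromics as sy
from syndromics.datasets import sci_motor_loadings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def example_loadings() -> sy.LoadingsTable:
    """The bundled 18-variable x 3-PC motor-outcome loading table."""
    return sci_motor_loadings()


@pytest.fixture
def planted_one_factor():
    """Factory: one-factor data (all loadings 0.8, noise sd 0.6)."""

    def make(n=100, v=6, loading=0.8, seed=0):
        noise = float(np.sqrt(1 - loading**2))
        model = sy.PlantedModel(
            n=n, L=sy.planted_loadings(v, 1, loading), noise_sd=noise, seed=seed
        )
        return sy.generate(model)

    return make


@pytest.fixture
def noise_data():
    """Factory: iid standard-normal data (no structure)."""

    def make(n=100, v=6, seed=0):
        rng = np.random.default_rng(seed)
        return sy.DataMatrix(
            rng.standard_normal((n, v)), [f"V{i+1}" for i in range(v)]
        )

    return make
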