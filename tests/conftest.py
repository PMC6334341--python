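import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from teaspec.synthetic import GeneratorConfig, generate_dataset

settings.register_profile(
    "fast", max_examples=25, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size study dataset: 12 classes x 10 samples, full grids."""
    return generate_dataset(GeneratorConfig(seed=0))


def small_config(**overrides) -> GeneratorConfig:
    """Reduced-grid config for fast unit tests (full wavenumber ranges,
    fewer grid points)."""
    defaults = dict(mir_points=240, nir_points=200, seed=0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
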