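import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from ghtnet.model import GHTNetConfig
from ghtnet.synthetic import generate_shape_table
from ghtnet.features import ShapeCatalog

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> GHTNetConfig:
    """A desk-scale model small enough for sub-second training steps."""
    return GHTNetConfig(d=8, n_heads=2, n_layers=1, cffn_hidden=16,
                        cffn_kernel=3, n_detectors=8, detector_width=11,
                        mlp_hidden=(16,))


@pytest.fixture(scope="session")
def shape_catalog() -> ShapeCatalog:
    return ShapeCatalog(generate_shape_table(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
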