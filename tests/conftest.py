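import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from flavochar.synthetic_data import SimConfig  # noqa: E402


@pytest.fixture
def noiseless():
    return SimConfig(seed=0, noise_rel=0.0)


@pytest.fixture
def protein_series():
    """Default 12-point apoprotein titration series, 0-1 µM."""
    return np.linspace(0.0, 1.0, 12)


@pytest.fixture
def fig6_design():
    """Flavin-reductase bisubstrate design: 8 NADH levels x 4 FMN levels."""
    return np.geomspace(5.0, 640.0, 8), np.array([10.0, 20.0, 50.0, 100.0])
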