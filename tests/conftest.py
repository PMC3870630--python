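"""Shared fixtures: phantoms and configuration reused across test modules."""

import numpy as np
import pytest

from vesseltrack import phantom
from vesseltrack.config import RunConfig


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def straight_noise_free():
    """Noise-free straight vessel (width 6, 20 degrees) with ground truth."""
    spec = phantom.straight_spec(width=6.0, angle_deg=20.0, seed=0)
    spec.sigma_v = spec.sigma_b = 0.0
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def straight_noisy():
    """Noisy straight vessel (width 6, 20 degrees, sigma 5) with truth."""
    return phantom.generate_phantom(phantom.straight_spec(width=6.0, angle_deg=20.0, seed=0))


@pytest.fixture(scope="session")
def y_junction_noisy():
    return phantom.generate_phantom(phantom.y_junction_spec(seed=0))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
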