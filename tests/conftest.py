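import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cropshift import (
    GridSpec,
    LandUseMask,
    SuitabilityGrid,
    bundled_requirements,
    generate_environment,
)


@pytest.fixture(scope="session")
def small_spec():
    return GridSpec(20, 40)


@pytest.fixture(scope="session")
def small_env(small_spec):
    return generate_environment(small_spec, seed=7)


@pytest.fixture(scope="session")
def maize_reqs():
    return bundled_requirements("maize")


def make_suitability(values, spec=None, period="baseline", crop="testcrop"):
    values = np.asarray(values, dtype=float)
    if spec is None:
        spec = GridSpec(*values.shape, lat_min=-60, lat_max=60, lon_min=-120, lon_max=120)
    return SuitabilityGrid(grid=spec, values=values, crop=crop, period=period)


def make_mask(fraction, spec=None):
    fraction = np.asarray(fraction, dtype=float)
    if spec is None:
        spec = GridSpec(*fraction.shape, lat_min=-60, lat_max=60, lon_min=-120, lon_max=120)
    return LandUseMask(grid=spec, fraction=fraction)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
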