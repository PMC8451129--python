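import numpy as np
import pytest

from cardiomicro.config import default_phantom_config
from cardiomicro.phantom import build_phantom


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-grid infarct-cohort phantom used across tests."""
    return default_phantom_config("infarct", grid_size=48, n_slices=3)


@pytest.fixture(scope="session")
def gt_day6(small_cfg):
    return build_phantom(small_cfg, "day6")


@pytest.fixture(scope="session")
def gt_baseline(small_cfg):
    return build_phantom(small_cfg, "baseline")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
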