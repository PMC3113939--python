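import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20110512)


@pytest.fixture(scope="session")
def side_cfg():
    from phenopipe.synthetic import build_view_config

    return build_view_config("side", 192, 240)


@pytest.fixture(scope="session")
def top_cfg():
    from phenopipe.synthetic import build_view_config

    return build_view_config("top", 192, 192)


def random_mask(rng, shape=(32, 32), density=0.35):
    return rng.random(shape) < density
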