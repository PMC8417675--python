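import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from carepath.simdata import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_patients=300, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_study(small_config)
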