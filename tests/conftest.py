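import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import neurorun as nr


@pytest.fixture(scope="session")
def desk_cfg():
    return nr.load_config(nr.load_profile("desk"))


@pytest.fixture(scope="session")
def desk_exp(desk_cfg):
    """Desk-scale experiment (active condition), shared read-only."""
    return nr.Experiment(desk_cfg)


@pytest.fixture(scope="session")
def desk_model(desk_exp):
    return desk_exp.model


@pytest.fixture(scope="session")
def fullscale_model():
    return nr.build_model(nr.fullscale_model_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
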