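import numpy as np
import pytest

import tftargets as t
from tftargets.pipeline import validation_config


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced synthetic-study config shared across end-to-end tests."""
    return validation_config(seed=11)


@pytest.fixture(scope="session")
def small_run(small_cfg, tmp_path_factory):
    """One full pipeline run on the validation fixture."""
    return t.run_all(small_cfg, tmp_path_factory.mktemp("run"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
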