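import numpy as np
import pytest

from lite3d.arch import reference_config
from lite3d.net import build_model
from lite3d.synthetic import SceneConfig, make_dataset


@pytest.fixture(scope="session")
def ref_cfg():
    """Reference architecture with the 5-behavior head."""
    return reference_config(5)


@pytest.fixture(scope="session")
def small_model(ref_cfg):
    """An untrained reference model with a fixed seed."""
    return build_model(ref_cfg, seed=123)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small labeled ROI-sequence set (4 per class) for plumbing tests."""
    return make_dataset(SceneConfig(seed=5), sequences_per_class=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
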