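import numpy as np
import pytest

from pmequant import synthgen as sg
from pmequant.config import AnalysisConfig


@pytest.fixture(scope="session")
def default_cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_shell_scene():
    """Small 3D axoneme scene shared across shell/membrane tests."""
    params = sg.Scene3DParams(
        shape=(32, 96, 96), n_puncta=200, punctum_radius_um=0.3, seed=11
    )
    return sg.make_axoneme_volume_3d(params)


@pytest.fixture(scope="session")
def small_vesicle_scene():
    """Small vesicle field: 20 vesicles, true positive fraction 0.85."""
    params = sg.Scene3DParams(
        shape=(40, 128, 128), n_vesicles=20, positive_fraction=0.85, seed=7
    )
    return sg.make_vesicle_volume_3d(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
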