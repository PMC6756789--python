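import numpy as np
import pytest

from doubletmech import (
    SceneParams,
    SubstrateModel,
    forward_displacement,
    make_doublet_scene,
    make_smooth_traction,
)


@pytest.fixture(scope="session")
def substrate():
    return SubstrateModel(30_000.0, 0.5, 1.0)


@pytest.fixture(scope="session")
def smooth_field(substrate):
    """A smooth zero-net-force traction field plus its displacement."""
    truth = make_smooth_traction((128, 128), 1.0, seed=3)
    return truth, forward_displacement(truth, substrate)


@pytest.fixture(scope="session")
def tugging_scene():
    """Doublet ground truth with a 50 nN transjunctional force."""
    return make_doublet_scene(SceneParams(f_tug=50.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
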