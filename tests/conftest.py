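import numpy as np
import pytest

from izmap.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def moderate_scene():
    """One full-size moderate-stage scene shared across tests."""
    return generate_scene(SceneParams(stage_group="moderate", seed=11))


@pytest.fixture(scope="session")
def advanced_scene():
    return generate_scene(SceneParams(stage_group="advanced", seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
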