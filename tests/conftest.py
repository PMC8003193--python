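import numpy as np
import pytest

from edgesharp import SceneSpec, render_scene


@pytest.fixture(scope="session")
def pair30():
    """Standard rendered scene: 30 deg zigzag, 12 px band-to-edge offset."""
    return render_scene(SceneSpec(turning_angle=30, edge_offset=12, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
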