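import warnings

import numpy as np
import pytest

from msreg.synthetic_data import SceneSpec, generate_scene


@pytest.fixture(autouse=True)
def _quiet_skimage_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One small synthetic scene shared by unit tests (not the benchmark size)."""
    spec = SceneSpec(
        shape=(200, 260),
        n_instances=6,
        instance_scale_px=(22.0, 60.0),
        warp_magnitude=10.0,
        seed=7,
    )
    scene, annotations = generate_scene(spec)
    return spec, scene, annotations
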