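import numpy as np
import pytest

from dockquant import pipeline
from dockquant.synthetic_scenes import OpticsParams, SceneParams, generate_scene


@pytest.fixture(scope="session")
def default_optics():
    return OpticsParams(voxel_size=2.2, noise_seed=1)


@pytest.fixture(scope="session")
def quiet_optics():
    return OpticsParams(voxel_size=2.2, noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_scene():
    """Three-junction scene, one of each morphology class."""
    params = SceneParams(n_junctions=3, class_probs=(1 / 3, 1 / 3, 1 / 3),
                         seed=123)
    return generate_scene(params)


@pytest.fixture(scope="session")
def single_junction():
    """One default junction plus its rendered noisy volume."""
    scene, gt = pipeline.single_junction_scene(2024)
    optics = OpticsParams(voxel_size=2.2, noise_seed=7)
    vol = pipeline.render_single_junction(scene, optics)
    return scene, gt, vol
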