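import numpy as np
import pytest

from fluorodroplet.synthetic_scenes import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_spec():
    """Smallest usable scene: a single trap in a 400 x 400 frame."""
    return SceneSpec(image_size=(400, 400), seed=3)


@pytest.fixture
def noiseless_single_cell_spec():
    """One droplet, exactly one live cell, no debris, no noise."""
    return SceneSpec(
        image_size=(400, 400),
        occupancy_distribution={1: 1.0},
        class_mix={"live": 1.0},
        debris_rate=0.0,
        free_cell_rate=0.0,
        noise_sigma=0.0,
        seed=5,
    )


@pytest.fixture
def single_cell_scene(noiseless_single_cell_spec):
    return generate_scene(noiseless_single_cell_spec)
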