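import numpy as np
import pytest

from endoheal.synthetic import SceneConfig, make_trajectory


@pytest.fixture
def clean_config():
    """Small artefact-free scene: zero noise, no islands/specks, flat fronts."""
    return SceneConfig(
        image_shape=(128, 128), n_frames=5, frame_interval=12.0,
        noise_sd=0.0, isolated_cell_rate=0.0, gap_rate=0.0,
        front_roughness=0.0, seed=7,
    )


@pytest.fixture
def noisy_config():
    """Small scene with the default photometric noise and artefact rates."""
    return SceneConfig(image_shape=(128, 128), n_frames=5, frame_interval=12.0, seed=7)


@pytest.fixture
def half_closing_trajectory():
    """Linear closure from a 60 µm half-width to half of it over 48 h."""
    return make_trajectory([0.0, 48.0], [1.0, 0.5], initial_half_width=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
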