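import numpy as np
import pytest

from echoscape import (
    IslandScene,
    SceneConfig,
    generate_echogram,
    generate_scene,
    generate_transects,
)


@pytest.fixture(scope="session")
def default_config():
    return SceneConfig(seed=7)


@pytest.fixture(scope="session")
def scene_and_field(default_config):
    return generate_scene(default_config)


@pytest.fixture(scope="session")
def scene(scene_and_field):
    return scene_and_field[0]


@pytest.fixture(scope="session")
def true_field(scene_and_field):
    return scene_and_field[1]


@pytest.fixture(scope="session")
def tracks(scene):
    return generate_transects(scene, 8)


@pytest.fixture(scope="session")
def echogram_pair(tracks, scene, true_field):
    """One transect's 70/200-kHz echograms with the ground-truth mask."""
    return generate_echogram(tracks[1], scene, true_field)


@pytest.fixture(scope="session")
def circle_scene():
    cfg = SceneConfig(seed=3, coast_a=1000.0, coast_b=1000.0, offshore_a=3000.0, offshore_b=3000.0)
    return IslandScene(cfg)


def rng(seed=0):
    return np.random.default_rng(seed)
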