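import numpy as np
import pytest

from mcsquant.synthetic import NoiseModel, SceneConfig, generate_ground_truth, render_scene


@pytest.fixture(scope="session")
def default_truth():
    return generate_ground_truth(SceneConfig(seed=3))


@pytest.fixture(scope="session")
def noise_free_scene(default_truth):
    return render_scene(default_truth, alpha=0.0, noise=None, mcs_er_baseline=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()
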