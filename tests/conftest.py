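import numpy as np
import pytest

from orchardet import PipelineConfig, SceneSpec, generate_scene
from orchardet.pipeline import default_components


@pytest.fixture(scope="session")
def default_spec():
    return SceneSpec()


@pytest.fixture(scope="session")
def scene(default_spec):
    """One deterministic synthetic scene shared across tests."""
    return generate_scene(default_spec, seed=5)


@pytest.fixture(scope="session")
def pipeline_setup(scene):
    """A default config + component bundle for the shared scene."""
    config = PipelineConfig(seed=5)
    return config, default_components(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def unit_vector(rng, dim=3):
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)
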