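import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from facesim.facespace import design_distances, enumerate_design
from facesim import model_zoo as mz
from facesim import synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design232():
    """The full 8 radii x 8 angles design (232 pairs)."""
    return enumerate_design(np.linspace(0, 40, 8), np.linspace(0, 180, 8))


@pytest.fixture(scope="session")
def distances232(design232):
    return pd.Series(
        design_distances(design232), index=pd.Index(design232.pair_ids, name="pair_id")
    )


@pytest.fixture(scope="session")
def trials232(design232):
    return sd.partition_trials(design232.pair_ids, 8, seed=0)


@pytest.fixture(scope="session")
def gen_map_small():
    """Small synthetic rendering map (latent dim 40, 8x8 images)."""
    return sd.make_generative_map(
        dim_latent=40, n_landmarks=10, image_size=8, n_mesh_vertices=20, seed=7
    )


@pytest.fixture(scope="session")
def stimuli232(design232):
    set_a, _ = sd.make_paired_stimulus_sets(design232, dim=60, seeds=(11, 12))
    return set_a


@pytest.fixture(scope="session")
def observer_default():
    return sd.ObserverSpec(seed=123)


@pytest.fixture(scope="session")
def dataset232(observer_default, distances232, trials232):
    """A default-observer judgment dataset over the 232-pair design."""
    return sd.simulate_observer(observer_default, distances232, trials232)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
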