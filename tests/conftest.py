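import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acquant import scenes

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def compact_spec(**overrides) -> scenes.SceneSpec:
    """A compact scene sharing the default geometry style but on a small
    grid, for fast unit tests."""
    base = dict(
        grid_shape=(16, 48, 80),
        voxel_size=(0.25, 0.1, 0.1),
        ac_center=(4.0, 2.0, 2.0),
        ac_radii=(1.2, 0.9, 0.9),
        protrusion=scenes.Protrusion(present=True, stalk_radius_um=0.6, length_um=0.8),
        bm_y_um=3.0,
        bm_gap_center_um=4.0,
        bm_gap_width_um=2.0,
        landmarks={
            "vulA1": (1.0, 3.8),
            "vulA2": (7.0, 3.8),
            "ac_edge_1": (3.3, 1.6),
            "ac_edge_2": (4.7, 1.6),
            "vulF_mid": (4.0, 4.2),
        },
    )
    base.update(overrides)
    return scenes.SceneSpec(**base)


@pytest.fixture
def small_spec() -> scenes.SceneSpec:
    return compact_spec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
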