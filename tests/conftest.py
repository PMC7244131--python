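import numpy as np
import pytest

from cropsuit import GridLayer, GridTransform, LayerStack, builtin_profile
from cropsuit.raster import PROJECTED


@pytest.fixture(scope="session")
def final_profile():
    return builtin_profile("breadfruit_final")


@pytest.fixture(scope="session")
def ecocrop_profile():
    return builtin_profile("breadfruit_ecocrop")


#: Values inside every optimal range of the breadfruit_final profile.
OPTIMAL_VALUES = {
    "temperature": 25.0,
    "rainfall": 2000.0,
    "solar_radiation": 120.0,
    "soil_ph": 6.0,
    "drainage_class": 5.0,
}


@pytest.fixture
def optimal_values():
    return dict(OPTIMAL_VALUES)


def make_stack(value_map, shape=(2, 2), cell=50.0, crs_kind=PROJECTED):
    """Aligned stack of constant (or array) layers, one per criterion."""
    transform = GridTransform(0.0, shape[0] * cell, cell, cell)
    layers = {}
    for name, v in value_map.items():
        arr = np.broadcast_to(np.asarray(v, dtype=float), shape).copy()
        layers[name] = GridLayer(
            values=arr, transform=transform, crs_kind=crs_kind, criterion=name
        )
    return LayerStack(layers)


@pytest.fixture
def optimal_stack(optimal_values):
    return make_stack(optimal_values)


def random_env_arrays(rng, shape):
    """Random per-criterion arrays spanning each criterion's plausible range."""
    return {
        "temperature": rng.uniform(5, 45, shape),
        "rainfall": rng.uniform(0, 10000, shape),
        "solar_radiation": rng.uniform(0, 350, shape),
        "soil_ph": rng.uniform(3, 10, shape),
        "drainage_class": rng.uniform(1, 7, shape),
    }
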