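import numpy as np
import pandas as pd
import pytest

from traitedge.synthetic_data import CoverModel, ScenarioConfig, generate_dataset
from traitedge.trait_space import TRAIT_NAMES, TraitTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_trait_table():
    """Four species exercising log, ordinal and tied values."""
    data = pd.DataFrame(
        {
            "height": [0.1, 1.0, 10.0, 2.0],
            "seed_mass": [0.5, 5.0, 50.0, 2.0],
            "leaf_area": [10.0, 100.0, 1000.0, 300.0],
            "sla": [5.0, 20.0, 80.0, 40.0],
            "ldmc": [100.0, 200.0, 400.0, 150.0],
            "flowering_midpoint": [5, 7, 7, 9],
            "flowering_length": [2.0, 3.0, 6.0, 4.0],
            "genome_size": [500.0, 1000.0, 4000.0, 2000.0],
        },
        index=pd.Index(["sp_a", "sp_b", "sp_c", "sp_d"], name="species"),
    )
    return TraitTable(data=data)


@pytest.fixture(scope="session")
def small_dataset():
    config = ScenarioConfig(
        n_native=120,
        n_naturalized=40,
        n_invasive=20,
        n_plots=25,
        richness_mean=10.0,
        scenario="neutral",
        cover_model=CoverModel(),
        seed=99,
    )
    return generate_dataset(config)


def random_fraction_coords(rng, n, dim=3):
    return rng.normal(size=(n, dim))


def brute_force_e(cx, cy, wx=None, wy=None):
    """Independent O(n^2) double-loop energy distance."""
    nx, ny = len(cx), len(cy)
    wx = np.full(nx, 1.0 / nx) if wx is None else np.asarray(wx) / np.sum(wx)
    wy = np.full(ny, 1.0 / ny) if wy is None else np.asarray(wy) / np.sum(wy)
    cross = same_x = same_y = 0.0
    for i in range(nx):
        for j in range(ny):
            cross += wx[i] * wy[j] * np.sqrt(np.sum((cx[i] - cy[j]) ** 2))
    for i in range(nx):
        for j in range(nx):
            if i != j:
                same_x += wx[i] * wx[j] * np.sqrt(np.sum((cx[i] - cx[j]) ** 2))
    for i in range(ny):
        for j in range(ny):
            if i != j:
                same_y += wy[i] * wy[j] * np.sqrt(np.sum((cy[i] - cy[j]) ** 2))
    return 2 * cross - same_x - same_y


def brute_force_d(coords, center, w=None):
    n = len(coords)
    w = np.full(n, 1.0 / n) if w is None else np.asarray(w) / np.sum(w)
    return sum(w[i] * np.sqrt(np.sum((coords[i] - center) ** 2)) for i in range(n))
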