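import numpy as np
import pandas as pd
import pytest

from azstorm.loc_io import LocalizationTable
from azstorm.simulate import SceneConfig, dye_preset, simulate_table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_table(x, y, frame, intensity, n_frames=15000, source_id="test"):
    return LocalizationTable(
        pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                      "frame": np.asarray(frame, int),
                      "intensity": np.asarray(intensity, float)}),
        n_frames=n_frames, source_id=source_id)


@pytest.fixture
def small_table():
    return make_table([5.0, 100.0, 250.0], [5.0, 120.0, 260.0],
                      [0, 1, 2], [3500.0, 4144.0, 9000.0])


@pytest.fixture(scope="session")
def af647_scene():
    """A compact simulated AF647 image shared across tests (read-only)."""
    cfg = SceneConfig(n_az=12, seed=7, field_size=(12000.0, 12000.0),
                      az_min_separation=1000.0)
    return simulate_table(cfg, dye_preset("AF647"))
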