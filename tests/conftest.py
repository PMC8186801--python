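import numpy as np
import pandas as pd
import pytest

from sfci import metric
from sfci.volumes import TimeSeriesVolume, VoxelGrid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    """An 8x8x6 grid with 2x2x4 mm voxels and an off-origin affine."""
    affine = np.diag([2.0, 2.0, 4.0, 1.0])
    affine[:3, 3] = [-8.0, -8.0, -12.0]
    return VoxelGrid(np.zeros((8, 8, 6)), affine)


@pytest.fixture()
def noise_series(rng):
    """A small white-noise 4-D series, TR 2.8 s."""
    data = rng.standard_normal((6, 6, 4, 40))
    return TimeSeriesVolume(data, np.diag([2.0, 2.0, 4.0, 1.0]), tr_s=2.8)


def make_measures(n_subjects=8, seed=0, prefix="c", fc_mean=1.5, sc_mean=0.5e-3):
    """A complete tidy measures frame covering all three pathways."""
    r = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for pathway in metric.PATHWAYS:
            rows.append({
                "subject": f"{prefix}{s:02d}", "visit": 0, "pathway": pathway,
                "fc": fc_mean + r.normal(0, 0.4),
                "sc": sc_mean + r.normal(0, 0.05e-3),
            })
    return pd.DataFrame(rows)


@pytest.fixture()
def control_measures():
    return make_measures(n_subjects=9, seed=7)
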