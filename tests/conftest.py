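import numpy as np
import pandas as pd
import pytest

from wmhnet.synthetic import SimulationConfig, make_atlas, make_streamlines
from wmhnet.volumes import LabeledVolume


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        grid_shape=(24, 24, 24),
        n_regions=6,
        n_streamlines=150,
        n_patients=12,
        pwmh_volume_ml=1.0,
        dwmh_volume_ml=0.5,
        stroke_volume_ml=1.0,
        pv_threshold_mm=6.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return make_atlas(small_config)


@pytest.fixture(scope="session")
def small_streamlines(small_config, small_atlas):
    return make_streamlines(small_atlas.atlas, small_config)


def random_binary_volume(rng, shape=(10, 10, 10), p=0.2, voxel=(1.0, 1.0, 1.0)):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel)
    return LabeledVolume((rng.random(shape) < p).astype(np.int16), aff)


def simulate_po_data(rng, n, beta, cutpoints):
    """Direct proportional-odds sampler used as an independent oracle."""
    p = len(beta)
    X = rng.normal(size=(n, p))
    latent = X @ np.asarray(beta) + rng.logistic(size=n)
    y = (latent[:, None] > np.asarray(cutpoints)[None, :]).sum(axis=1)
    return y, X


@pytest.fixture
def cohort_frame(rng):
    n = 40
    return pd.DataFrame({
        "patient_id": [f"p{i:03d}" for i in range(n)],
        "age": rng.normal(70, 10, n),
        "nihss": rng.integers(1, 18, n),
        "mrs": rng.integers(0, 5, n),
        "lesion_volume_ml": rng.lognormal(np.log(20), 0.5, n),
        "wmh_volume_ml": rng.lognormal(np.log(10), 0.4, n),
    })
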