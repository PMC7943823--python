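import numpy as np
import pandas as pd
import pytest

from canopyedge.synthetic import SceneConfig, TerrainConfig, generate_scene


@pytest.fixture(scope="session")
def small_cfg() -> SceneConfig:
    """A 3 x 3 km scene: every landscape feature present, fast to generate."""
    return SceneConfig(seed=7, extent_m=(3000.0, 3000.0))


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    return generate_scene(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230915)


def make_pixel_frame(n, rng, noise_sd=0.0, spatial_range=None, extent=6000.0,
                     truth=(0.6576, -0.02142, -0.0172, 0.8553, 0.0049)):
    """Synthetic pixel table with scene-like covariates and optional noise."""
    from canopyedge.edgemodel import ModelSpec

    xy = rng.uniform(0, extent, (n, 2))
    tpi = rng.normal(0, 7.0, n)
    tch = rng.uniform(0, 64.0, n)
    d = rng.uniform(0, 4000.0, n)
    spec = ModelSpec("asymptotic", "asymptotic")
    y = spec.predict(np.asarray(truth), tpi, tch, d)
    if noise_sd > 0:
        if spatial_range:
            from scipy.spatial.distance import pdist, squareform

            C = np.exp(-squareform(pdist(xy)) / spatial_range)
            L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
            y = y + noise_sd * (L @ rng.standard_normal(n))
        else:
            y = y + noise_sd * rng.standard_normal(n)
    return pd.DataFrame(
        {"delta_tch": y, "tpi": tpi, "tch_2014": tch, "d_edge": d,
         "x": xy[:, 0], "y": xy[:, 1]}
    )
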