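import numpy as np
import pandas as pd
import pytest

from cetadens.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset with planted drivers, shared across tests."""
    cfg = SimConfig(p_asvs=120, driver_count=3, sigma_eps=0.1, seed=7)
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def hn_distances():
    """500 perpendicular distances from a half-normal detection process,
    sigma = 1000 m, truncated at 2400 m, as a sightings table."""
    rng = np.random.default_rng(11)
    w, sigma = 2400.0, 1000.0
    x = []
    while len(x) < 500:
        cand = rng.uniform(0, w, 4000)
        keep = rng.uniform(size=4000) < np.exp(-cand**2 / (2 * sigma**2))
        x.extend(cand[keep].tolist())
    return pd.DataFrame({
        "cruise": "c1", "transect": "t1", "species": "whale",
        "distance_m": np.array(x[:500]), "group_size": 1,
        "beaufort": 2, "swell_m": 1.0, "platform": "mid",
    })
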