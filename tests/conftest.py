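import numpy as np
import pandas as pd
import pytest

from dynsad import CommunityTable, SimulationConfig, simulate
from dynsad.model import DynamicSADModel, ModelSpec


@pytest.fixture
def toy_table():
    """Two species, two years, one site; species B unseen in year 1."""
    df = pd.DataFrame(
        {
            "species": ["A", "A", "B"],
            "time": [0.0, 1.0, 0.0],
            "location": ["L1", "L1", "L1"],
            "replicate": [0, 0, 0],
            "count": [3, 5, 2],
        }
    )
    return CommunityTable(df)


@pytest.fixture
def two_site_table():
    """Two locations with habitat metadata for splitting tests."""
    df = pd.DataFrame(
        {
            "species": ["A", "B", "A", "C"],
            "time": [0.0, 0.0, 0.0, 0.0],
            "location": ["L1", "L1", "L2", "L2"],
            "replicate": [0, 0, 0, 0],
            "count": [1, 4, 2, 7],
        }
    )
    locations = pd.DataFrame(
        {
            "latitude": [0.0, 0.5],
            "longitude": [0.0, 0.5],
            "habitat": ["forest", "fragment"],
        },
        index=pd.Index(["L1", "L2"], name="location"),
    )
    return CommunityTable(df, locations)


@pytest.fixture(scope="session")
def small_community():
    """Weak-regulation simulated community reused across model tests."""
    g = 0.1
    cfg = SimulationConfig(
        n_species=15,
        n_steps=335,
        burn_in=320,
        gamma=g,
        mu_r=5 * g,
        sigma2_r=g**2 * 0.6,
        sigma2_s=2 * g * 0.4,
        sigma2_E=2 * g * 0.1,
        nu=1.0,
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_fit(small_community):
    model = DynamicSADModel(small_community.to_table(), ModelSpec())
    return model.fit(seed=0, n_starts=1)
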