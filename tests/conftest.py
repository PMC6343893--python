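import numpy as np
import pandas as pd
import pytest

from satregions import SimConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A quick default-calibration map: 800 tracts, ~45k respondents."""
    return SimConfig(n_tracts=800, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    tracts, individuals = simulate(small_config)
    return tracts, individuals


def random_tracts(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A bare random tract table for partition fuzzing."""
    counts = rng.integers(1, 200, size=n)
    return pd.DataFrame(
        {
            "tract_id": [f"T{i:05d}" for i in range(n)],
            "x": rng.uniform(0, 50, size=n),
            "y": rng.uniform(0, 50, size=n),
            "n_k": counts,
            "w_k": counts * rng.uniform(50, 150, size=n),
        }
    )
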