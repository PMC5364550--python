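import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from utakit import ReducedParams, SimulationConfig, simulate_events


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noise_free_config():
    """Identity-mapping generator: no miRNA, no noise, no autofluorescence."""
    return SimulationConfig(
        seed=11,
        theta=0.0,
        lam=1.0,
        n_events=2000,
        meas_log_sd=0.0,
        af_mean=0.0,
        af_sd=0.0,
        untransfected_fraction=0.0,
    )


@pytest.fixture
def default_events():
    """One default-noise sample with a mid-regime miRNA."""
    return simulate_events(SimulationConfig(seed=3, theta=100.0, lam=10.0, n_events=20_000))


@pytest.fixture
def small_event_table():
    return pd.DataFrame(
        {
            "event_id": [0, 1, 2],
            "sample_id": ["s", "s", "s"],
            "ref_intensity": [10.0, 100.0, 1000.0],
            "rep_intensity": [5.0, 50.0, 500.0],
        }
    )


@pytest.fixture
def mid_params():
    return ReducedParams(theta=5.0, lam=1.0)
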