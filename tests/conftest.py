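import numpy as np
import pandas as pd
import pytest

from attanest import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study for fast pipeline tests (same structure, fewer days)."""
    return synth.SyntheticConfig(seed=11, days_per_month=4, nests_per_env=40)


@pytest.fixture(scope="session")
def small_study(small_config):
    return synth.simulate_study(small_config)


@pytest.fixture
def day_of_samples():
    """One calendar day of accepted 5-minute samples at a constant 1000 W/m^2."""
    ts = pd.date_range("2019-11-05", periods=288, freq="5min")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "component": "GHI",
            "value_wm2": 1000.0,
            "accepted": True,
        }
    )
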