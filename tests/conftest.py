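import numpy as np
import pandas as pd
import pytest

from strokecast.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 900-day null synthetic district (no planted meteo effect)."""
    cfg = SyntheticConfig(seed=42, n_days=900)
    counts, meteo = generate_dataset(cfg)
    return counts, meteo


@pytest.fixture
def daily_index():
    def make(n, start="2015-01-01"):
        return pd.date_range(start, periods=n, freq="D")
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
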