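import numpy as np
import pandas as pd
import pytest

from pydlnm import SimConfig, simulate_dataset


def seasonal_confounders(n: int) -> pd.DataFrame:
    """Annual harmonic pair matching the simulated baseline's seasonal shape."""
    t = np.arange(n)
    return pd.DataFrame(
        {
            "cos1": np.cos(2 * np.pi * t / 365.25),
            "sin1": np.sin(2 * np.pi * t / 365.25),
        }
    )


@pytest.fixture(scope="session")
def sim_small():
    """A modest simulated series shared by fitting tests."""
    cfg = SimConfig(n_days=2000, surface="ushape_decay", dispersion=1.5, max_lag=10, seed=42)
    return cfg, simulate_dataset(cfg)
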