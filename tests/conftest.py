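import numpy as np
import pandas as pd
import pytest

from deapanel.synthetic import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """Default-condition synthetic panel (242 jurisdictions, 2009-2020)."""
    cfg = SyntheticConfig(seed=1)
    panel, truth = generate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def noisefree_small_panel():
    """Single noise-free year, 100 jurisdictions: exact frontier recovery setting."""
    cfg = SyntheticConfig(
        n_jurisdictions=100, years=(2009, 2009), noise_scale=0.0, seed=11
    )
    panel, truth = generate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dea_instance(seed, n=10, p=2, q=2):
    """Positive random inputs/outputs for property tests."""
    r = np.random.default_rng(seed)
    X = r.uniform(0.5, 4.0, (n, p))
    Y = r.uniform(0.5, 4.0, (n, q))
    return X, Y
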