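import numpy as np
import pytest

from ppfil import data as pdata
from ppfil import linear


@pytest.fixture
def small_binary():
    """Normalized binary dataset with 3 informative of 8 features."""
    spec = pdata.SyntheticSpec(
        n_samples=200, m_features=8, k_informative=3, effect_size=2.0, seed=1
    )
    raw = pdata.generate_synthetic_tabular(spec)
    train, test = pdata.train_test_split(raw, 0.2, seed=1)
    norm = pdata.fit_minmax(train)
    return pdata.apply_minmax(train, norm), pdata.apply_minmax(test, norm)


@pytest.fixture
def tiny_spec():
    return linear.LinearModelSpec(n_features=4, n_classes=3)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
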