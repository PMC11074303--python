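import numpy as np
import pytest

from splitthz import phantom


@pytest.fixture(scope="session")
def recovery_data():
    """n=2000 synthetic ordinal-probit pixels from known beta and cutpoints."""
    rng = np.random.default_rng(42)
    beta = np.array([1.5, -0.7])
    cutpoints = np.array([-0.5, 0.8])
    Z = rng.standard_normal((2000, 2))
    u = Z @ beta + rng.standard_normal(2000)
    ci = np.searchsorted(cutpoints, u)
    y = np.array(phantom.CLASS_CODES)[ci]
    return Z, y, beta, cutpoints


@pytest.fixture(scope="session")
def phantom_task():
    """A 200-pixel, 8-band training task from a small labeled phantom."""
    cfg = phantom.default_config(32, 32, 8, seed=5)
    ph = phantom.generate_phantom(cfg)
    tab = phantom.to_pixel_table(ph)
    rng = np.random.default_rng(6)
    rows = np.sort(rng.choice(tab.n, 200, replace=False))
    return tab.X[rows], tab.y[rows]


@pytest.fixture()
def small_phantom():
    cfg = phantom.default_config(32, 32, 16, seed=11)
    return phantom.generate_phantom(cfg)
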