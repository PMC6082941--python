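import numpy as np
import pytest

from indelpanel.simulate import dongxiang_like_panel, simulate_balding_nichols


@pytest.fixture(scope="session")
def panel_gm():
    """HWE panel simulated at the published 30-locus frequencies (n = 169)."""
    return dongxiang_like_panel(seed=20180802)


@pytest.fixture(scope="session")
def two_pop_gm():
    """Two moderately diverged populations for divergence/topology tests."""
    return simulate_balding_nichols(100, 50, 0.15, seed=4021, n_pops=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
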