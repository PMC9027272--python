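import numpy as np
import pytest

import rpworld as rp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def interior_params():
    """Parameters with 0 < m < 1 and a comfortably positive margin."""
    return rp.PDEParams(aR=1.0, aP0=0.5, dR=0.01, dP=0.01, m=0.01, n0=1.0,
                        sigma_a=0.0)


@pytest.fixture
def gentle_params():
    """Slow dynamics near the fixed point: forward Euler at dt=0.1 stays
    accurate and the per-step resource cap is never active."""
    return rp.PDEParams(aR=1.0, aP0=0.5, dR=0.01, dP=0.01, m=0.01, n0=0.01,
                        sigma_a=0.0, dt=0.1)


@pytest.fixture
def small_mas_params():
    return rp.MASParams(sizeX=100.0, sizeY=100.0, n_replicases0=40,
                        n_parasites0=40, time_limit=50, seed=7)
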