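import numpy as np
import pytest

import mriwater as mw


@pytest.fixture(scope="session")
def brain48():
    """Noiseless 48^3 brain phantom with simulated low/high echo trains."""
    bp = mw.make_brain_phantom(grid=(48, 48, 48))
    low = mw.simulate_megre(bp.spec, mw.MEGRE_LOW, seed=1)
    high = mw.simulate_megre(bp.spec, mw.MEGRE_HIGH, seed=2)
    return bp, low, high


@pytest.fixture(scope="session")
def brain48_maps(brain48):
    """Relaxometry maps fitted with the true transmit field."""
    bp, low, high = brain48
    t1map = mw.fit_t1_two_point(low, high, bp.spec.b1plus_true)
    t2map = mw.fit_t2star(low)
    return t1map, t2map


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
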