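import numpy as np
import pytest

from gsdsnn.crossbar import SynapseArray
from gsdsnn.device_model import BETA_FLOOR, pinned_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pinned_b1():
    """Unit-range pinned device with beta = 1 on both branches, t_max = 1."""
    return pinned_params(1.0, 1.0, t_max=1.0)


@pytest.fixture
def linear_device():
    """Near-linear pinned device (beta at the floor), t_max = 0.1 s."""
    return pinned_params(BETA_FLOOR, BETA_FLOOR, t_max=0.1)


@pytest.fixture
def make_array(linear_device):
    """Factory for a crossbar with prescribed signed weights (linear devices)."""

    def _make(W, params=None, variation=None, seed=0):
        W = np.asarray(W, dtype=float)
        kw = {} if variation is None else {"variation": variation}
        arr = SynapseArray.create(
            W.shape[0], W.shape[1], params or linear_device,
            rng=np.random.default_rng(seed), init="floor", **kw,
        )
        arr.set_weights(W)
        return arr

    return _make
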