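import numpy as np
import pytest

from spikescale.io import SpikeTrain
from spikescale.timescales import BinnedTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def poisson_train(rng):
    """20-minute homogeneous Poisson spike train at ~4 Hz."""
    duration = 1200.0
    n = rng.poisson(4.0 * duration)
    times = np.sort(rng.uniform(0, duration, n))
    times = np.unique(times)
    return SpikeTrain("poisson", times, 0.0, duration)


def markov_binary(n, p11, p01, rng):
    """Two-state Markov chain with P(1->1)=p11, P(0->1)=p01."""
    a = np.empty(n, dtype=np.int8)
    a[0] = 0
    u = rng.random(n)
    for t in range(1, n):
        p = p11 if a[t - 1] else p01
        a[t] = u[t] < p
    return a


@pytest.fixture
def markov_train(rng):
    """240,000-bin realization of the (0.8, 0.2) chain at dt = 5 ms."""
    a = markov_binary(240_000, 0.8, 0.2, rng)
    return BinnedTrain(a, 5.0, len(a) * 5.0)
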