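import numpy as np
import pytest

from gbcpop.model import SpikeData


def make_spikes(trials, duration=25.0):
    """SpikeData from a list of per-trial spike-time lists."""
    return SpikeData(trials=[np.asarray(t, dtype=float) for t in trials],
                     trial_duration=duration)


@pytest.fixture
def periodic_train():
    """One trial firing exactly once per cycle of a 200 Hz reference (5 ms)."""
    return make_spikes([np.arange(1.0, 25.0, 5.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
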