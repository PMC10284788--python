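import numpy as np
import pytest

from arousalkit.signal_io import MultiChannelSignal


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_signal(rng):
    """10 s of 6-channel noise at 128 Hz."""
    data = rng.standard_normal((1280, 6)) * 10.0
    return MultiChannelSignal(
        data, fs=128.0,
        channel_names=["F3", "F4", "AF3", "AF4", "FT9", "FT10"],
    )
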