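import numpy as np
import pytest

from aperiodic_net import montage
from aperiodic_net.preprocess import Recording


@pytest.fixture(scope="session")
def biosemi():
    labels, coords = montage.biosemi32()
    return labels, coords


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(data, sfreq=512.0, segments=None):
    """Recording on a generic ring montage, for module-level tests."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch = data.shape[1]
    labels, coords = montage.ring_montage(n_ch)
    return Recording(
        data=data, sfreq=sfreq, labels=labels, coords=coords,
        segments=list(segments) if segments else [],
    )


@pytest.fixture()
def sine_recording():
    """Unit-amplitude 10 Hz sinusoid, 60 s at 512 Hz, two channels."""
    t = np.arange(60 * 512) / 512.0
    x = np.sin(2 * np.pi * 10 * t)
    return make_recording(np.column_stack([x, x]))
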