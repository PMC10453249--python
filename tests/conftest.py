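import numpy as np
import pytest

from vpidet.psdr import AveragedPSDR


@pytest.fixture
def make_avg():
    """Factory for an AveragedPSDR with a given rbar curve (index 0 = DC)."""
    def _make(rbar, fs=11025.0, Ns=256):
        rbar = np.asarray(rbar, dtype=np.float64)
        delta = fs / Ns
        return AveragedPSDR(rbar=rbar, Nf_used=1,
                            freqs=np.arange(len(rbar)) * delta,
                            delta_omega=delta, fs=fs)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
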