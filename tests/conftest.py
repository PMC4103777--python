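import numpy as np
import pytest

from cardioetho.core import Trace
from cardioetho.synth import CardioSimParams, generate_pap


@pytest.fixture(scope="session")
def clean_pap():
    """A 2-min noiseless, modulated arterial trace with its truth table."""
    params = CardioSimParams(duration_s=120.0, lf_amp_mmHg=5.0,
                             resp_amp_mmHg=2.0, noise_sd_mmHg=0.0,
                             noise_sd_ms=0.0, seed=21)
    trace, truth = generate_pap(params)
    return params, trace, truth


@pytest.fixture(scope="session")
def noisy_pap():
    """A 2-min realistic arterial trace (default noise) with truth."""
    params = CardioSimParams(duration_s=120.0, seed=3)
    trace, truth = generate_pap(params)
    return params, trace, truth


@pytest.fixture()
def sinusoid_trace():
    """110 + 15 sin(2 pi 6 t) mmHg at 1 kHz for 10 s: 60 'beats' with
    analytically known SABP/DABP/MABP/PI."""
    t = np.arange(0, 10, 0.001)
    return Trace(110 + 15 * np.sin(2 * np.pi * 6 * t), fs_hz=1000.0)
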