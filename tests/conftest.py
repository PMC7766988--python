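import numpy as np
import pytest

from beatkit import EcgSimSpec, PpgSimSpec, gen_ecg, gen_ppg


@pytest.fixture(scope="session")
def clean_ecg():
    """60 s of clean synthetic ECG at 60 bpm, 250 Hz, with R truth."""
    return gen_ecg(EcgSimSpec(hr=60, duration=60, fs=250, seed=1))


@pytest.fixture(scope="session")
def clean_ppg():
    """60 s of clean synthetic PPG at 60 bpm, 125 Hz, with full truth."""
    return gen_ppg(PpgSimSpec(hr=60, duration=60, fs=125, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
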