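import numpy as np
import pytest
from scipy import signal

from oscinet import ALPHA, BandSpec, TimeSeriesBlock

FS = 250.0


def narrowband(seed: int, n_samples: int = 45_000, band: BandSpec = ALPHA,
               fs: float = FS) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise channel."""
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, [band.f_lo / (fs / 2), band.f_hi / (fs / 2)],
                        btype="bandpass", output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def tone(freq: float, duration: float = 10.0, fs: float = FS,
         amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


@pytest.fixture
def alpha_pair():
    """Two independent 180-s alpha-band channels."""
    return narrowband(11), narrowband(22)


@pytest.fixture
def white_ts():
    rng = np.random.default_rng(7)
    return TimeSeriesBlock(data=rng.standard_normal((3, int(180 * FS))), fs=FS,
                           labels=["a", "b", "c"], kind="roi")
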