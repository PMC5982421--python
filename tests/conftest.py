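import numpy as np
import pytest

from fdbdrill.spectral import BandSpectrum

BAND_FREQS = np.arange(117, 175) * 44_000 / 512  # the 58 analysis bins


@pytest.fixture(scope="session")
def band_freqs():
    return BAND_FREQS


def make_band_spectrum(amplitudes, time=0.0):
    return BandSpectrum(time=time, freqs=BAND_FREQS[: len(amplitudes)],
                        amplitudes=amplitudes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
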