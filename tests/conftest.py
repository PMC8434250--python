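import numpy as np
import pytest

from ramandecomp import Spectrum


@pytest.fixture
def gaussian_spectrum():
    """Single noiseless Gaussian (center 700, h 1, FWHM 12) on 600-800."""
    x = np.arange(600.0, 800.0, 0.5)
    y = np.exp(-4 * np.log(2) * ((x - 700.0) / 12.0) ** 2)
    return Spectrum(x, y)


@pytest.fixture
def flat_spectrum():
    x = np.arange(300.0, 2000.0, 1.0)
    return Spectrum(x, np.zeros_like(x))
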