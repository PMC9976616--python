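import numpy as np
import pytest

from woi import io_mask_atlas as io
from woi import preprocess as pp


@pytest.fixture(scope="session")
def spectra():
    """Packaged extinction table and LED tables keyed by nominal wavelength."""
    paths = io.packaged_spectra_paths()
    ext = io.read_spectra(paths["extinction"])
    leds = {wl: io.read_spectra(paths[f"led_{wl}"]) for wl in (470, 530, 590, 625)}
    return ext, leds


@pytest.fixture(scope="session")
def model(spectra):
    ext, leds = spectra
    return pp.build_spectroscopy_model(ext, leds)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_mask():
    return io.BrainMask(np.ones((16, 16), bool))
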