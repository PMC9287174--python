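import numpy as np
import pytest

from fp_photodyn import load_reference_spectra


@pytest.fixture(scope="session")
def spectra():
    """Published photophysics table of the five green-emitting proteins."""
    return load_reference_spectra()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
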