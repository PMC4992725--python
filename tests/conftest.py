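import numpy as np
import pytest

from nigrascan.phantom import default_nm_spec, make_nm_phantom, nm_layout


@pytest.fixture(scope="session")
def exact_phantom():
    """Noiseless checkerboard phantom: every chain value has a closed form.

    SN volume 236 mm^3 / CNR 4.28, LC CNR 3.54 (the PD contralateral
    group means), parity-balanced rectangular reference ROIs.
    """
    spec = default_nm_spec(sn_volume_mm3=236.0, sn_cnr=4.28, lc_cnr=3.54,
                           noise_sd=0.0, texture="checkerboard")
    return make_nm_phantom(spec), nm_layout(spec, exact=True)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Realistic phantom: Gaussian noise at the background SD, circle ROIs."""
    spec = default_nm_spec(sn_volume_mm3=344.0, sn_cnr=4.91, lc_cnr=4.89,
                           noise_sd=10.0, seed=42)
    return make_nm_phantom(spec), nm_layout(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
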