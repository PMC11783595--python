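import numpy as np
import pytest

from barrelfret.spectra import DPH, NILE_RED, make_spectra


@pytest.fixture(scope="session")
def dye_spectra():
    """(donor emission, donor extinction, acceptor emission, acceptor extinction)
    for the default DPH / Nile red pair on a 1 nm grid."""
    grid = np.arange(300.0, 750.0, 1.0)
    d_em, d_ext = make_spectra(DPH, grid)
    a_em, a_ext = make_spectra(NILE_RED, grid)
    return d_em, d_ext, a_em, a_ext
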