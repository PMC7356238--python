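import numpy as np
import pytest

from hsoi import colorimetry as cm
from hsoi.phantom import PhantomSpec, generate_checker_spectra, generate_fundus_phantom


@pytest.fixture(scope="session")
def cmf():
    return cm.load_cmf()


@pytest.fixture(scope="session")
def d65():
    return cm.load_d65()


@pytest.fixture(scope="session")
def checker_rank6():
    """24 smooth random checker spectra of full spectral rank 6."""
    return generate_checker_spectra(seed=1, basis_dim=6)


@pytest.fixture(scope="session")
def checker_rank3():
    return generate_checker_spectra(seed=1, basis_dim=3)


@pytest.fixture(scope="session")
def phantom_default():
    """The default noiseless fundus phantom (seed 0)."""
    return generate_fundus_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
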