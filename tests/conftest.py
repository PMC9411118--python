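import numpy as np
import pytest

from leafphos import KineticConstants, LeafBiochem
from leafphos.synthetic import gen_aci_curve


@pytest.fixture(scope="session")
def kin():
    """Default Bernacchi kinetics with Tgrowth = 25 degC."""
    return KineticConstants()


@pytest.fixture(scope="session")
def biochem():
    """Reference leaf: Vcmax25=50, Jmax25=100, Rd25=1 umol m-2 s-1."""
    return LeafBiochem(50.0, 100.0, 1.0)


@pytest.fixture
def noiseless_curve(biochem):
    return gen_aci_curve(biochem, seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def ci_grid():
    return np.array([50., 100., 150., 200., 275., 400., 600., 800.,
                     1000., 1250., 1500.])
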