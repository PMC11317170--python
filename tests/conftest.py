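import numpy as np
import pytest

from dnamech import EmpiricalParams, PolymerParams, ThermalConstants
from dnamech.synthetic_data import SimulationConfig, gen_fec_empirical


@pytest.fixture
def thermal():
    return ThermalConstants()


@pytest.fixture
def empirical_params():
    """A representative parameter set for a bare-dsDNA stretch curve."""
    return EmpiricalParams(p1=16.2, p2=0.3, p3=2.0, p4=60.0, p5=32.0, p6=10.0)


@pytest.fixture
def dsdna_params():
    return PolymerParams(lc_um=16.37, lp_nm=50.0, kappa_pn=1200.0)


@pytest.fixture
def noiseless_fec(empirical_params):
    grid = np.arange(10.0, 0.97 * empirical_params.p5, 0.1)
    return gen_fec_empirical(
        empirical_params,
        SimulationConfig(seed=0, force_noise_sd=0.0, extension_grid=grid),
    )
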