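import pytest

from hillmuscle import CEParams, design_params_for, load_catalog
from hillmuscle.mtu import MTUParams


@pytest.fixture(scope="session")
def catalog():
    return {e.name: e for e in load_catalog()}


@pytest.fixture(scope="session")
def piglet(catalog):
    """CE design parameters for the piglet gastrocnemius (k_SE = 2401 N/m)."""
    return design_params_for(catalog["Piglet gastrocnemius"])


@pytest.fixture(scope="session")
def tibialis():
    """Human tibialis anterior MTU parameter set (the packaged defaults)."""
    return MTUParams()


@pytest.fixture
def simple_ce():
    """Small, fast CE for dynamics unit tests (short time constants)."""
    return CEParams(F_AE_max=30.0, R_PDE=0.2, D_PDE=100.0, k_SE=1000.0,
                    l_SE_slack=0.05, l_CE_init=0.30)
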