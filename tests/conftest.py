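import numpy as np
import pytest

from mrst2.cohort import default_moieties
from mrst2.spin_sim import AcquisitionScheme, build_basis_set


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme()


@pytest.fixture(scope="session")
def basis(scheme):
    """Default 7-TE basis over all registry moieties (simulated once)."""
    return build_basis_set(default_moieties(), scheme, linewidth=12.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231002)
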