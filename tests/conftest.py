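import numpy as np
import pytest

from qbold.models import (AcquisitionProtocol, BloodCompartment,
                          TissuePhysiology)


@pytest.fixture(scope="session")
def proto():
    """Default 3 T protocol: TE 74 ms, 24-point tau schedule."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def blood():
    return BloodCompartment()


@pytest.fixture(scope="session")
def phys():
    """Reference grey-matter physiology: OEF 40%, DBV 3%."""
    return TissuePhysiology(oef=0.40, dbv=0.03)


@pytest.fixture(scope="session")
def clean_signal(phys, blood, proto):
    from qbold.simulate import simulate_signal
    return simulate_signal(phys, blood, proto)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
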