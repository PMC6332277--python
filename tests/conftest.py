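import pytest

from qnmr import (
    AcquisitionParams,
    MixtureSpec,
    default_regions,
    synthesize_spectrum,
)
from qnmr.datasets import tadalafil_dnt_system


@pytest.fixture(scope="session")
def system():
    """(analyte, internal standard) = (tadalafil, 2,4-DNT)."""
    return tadalafil_dnt_system()


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def regions(system, params):
    return default_regions(list(system), params)


@pytest.fixture(scope="session")
def equal_mass_spectrum(system):
    """Noiseless 5 mg + 5 mg mixture spectrum, shared across tests."""
    analyte, standard = system
    spec = MixtureSpec(components=((analyte, 5.0), (standard, 5.0)))
    return synthesize_spectrum(spec)
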