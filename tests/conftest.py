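import pytest
from hypothesis import settings

settings.register_profile("foilyield", deadline=None, derandomize=True)
settings.load_profile("foilyield")

from foilyield.activation import MonitorTable
from foilyield.io import load_xs_fixture
from foilyield.nuclides import default_registry, load_thresholds


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def xs_table():
    return load_xs_fixture()


@pytest.fixture(scope="session")
def thresholds():
    return load_thresholds()


@pytest.fixture(scope="session")
def monitor():
    return MonitorTable.natni_ni57()


# Reference proton mass stopping powers (MeV cm^2/g), computed once with
# an independent full-relativistic Bethe evaluation (exact maximum energy
# transfer including projectile-mass terms) at the same mean excitation
# energies. Frozen here as the oracle for the production stopping model.
STOPPING_REFERENCE = {
    "Ti": {10: 30.418126, 15: 22.237424, 20: 17.766552, 30: 12.934028,
           40: 10.332671, 50: 8.692456, 60: 7.558085, 70: 6.724225},
    "Al": {10: 34.278686, 15: 24.918352, 20: 19.839297, 30: 14.381151,
           40: 11.458072, 50: 9.621013, 60: 8.353458, 70: 7.423344},
    "Ni": {10: 29.556686, 15: 21.726868, 20: 17.416978, 30: 12.731680,
           40: 10.196881, 50: 8.593566, 60: 7.482225, 70: 6.663905},
}


@pytest.fixture(scope="session")
def stopping_reference():
    return STOPPING_REFERENCE
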