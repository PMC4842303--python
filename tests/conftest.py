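import pytest

from confold import NearestNeighborModel, ThermoParams


@pytest.fixture(scope="session")
def model():
    return NearestNeighborModel.default()


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams()
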