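import pytest

from mammocea.lifetables import (
    synth_lifetable,
    synth_post75_incidence,
    synth_utilities,
)
from mammocea.model import ScreeningCEModel
from mammocea.params import (
    EconomicSettings,
    default_cancer_params,
    default_cost_params,
    default_screening_params,
)
from mammocea.strategies import make_base_aidm, make_base_cdm


@pytest.fixture(scope="session")
def screening():
    return default_screening_params()


@pytest.fixture(scope="session")
def costs():
    return default_cost_params()


@pytest.fixture(scope="session")
def cancer():
    return default_cancer_params()


@pytest.fixture(scope="session")
def lifetable():
    return synth_lifetable()


@pytest.fixture(scope="session")
def utilities():
    return synth_utilities()


@pytest.fixture(scope="session")
def incidence():
    return synth_post75_incidence()


@pytest.fixture(scope="session")
def settings():
    return EconomicSettings()


@pytest.fixture(scope="session")
def aidm(screening, costs):
    return make_base_aidm(screening, costs)


@pytest.fixture(scope="session")
def cdm(screening, costs):
    return make_base_cdm(screening, costs)


@pytest.fixture(scope="session")
def base_model():
    return ScreeningCEModel.from_defaults()


@pytest.fixture(scope="session")
def base_fit(base_model):
    return base_model.fit()
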