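import pytest

from fusiondx.annotation import PartnerDomainCatalog
from fusiondx.cohort import build_reference_model
from fusiondx.assays import default_designs
from fusiondx.model import build_fgfr2_fixture


@pytest.fixture(scope="session")
def reference():
    """(GeneModel, PartnerDomainCatalog): FGFR2 fixture + toy partner genes."""
    return build_reference_model()


@pytest.fixture(scope="session")
def model(reference):
    return reference[0]


@pytest.fixture(scope="session")
def catalog(reference):
    return reference[1]


@pytest.fixture(scope="session")
def fgfr2_only():
    return build_fgfr2_fixture()


@pytest.fixture(scope="session")
def designs(model):
    return default_designs(model)
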