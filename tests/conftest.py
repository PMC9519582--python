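import numpy as np
import pytest

from stromasim.cell_models import build_caf_network, build_cancer_cell_network


@pytest.fixture(scope="session")
def cancer_spec():
    return build_cancer_cell_network()


@pytest.fixture(scope="session")
def caf_spec():
    return build_caf_network()


@pytest.fixture(scope="session", params=["cancer", "caf"])
def cell_spec(request, cancer_spec, caf_spec):
    return cancer_spec if request.param == "cancer" else caf_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
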