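import numpy as np
import pytest

from isodiet import build_tef_set, study_data


@pytest.fixture(scope="session")
def study_groups():
    """The five study end-member groups (bivalves pooled)."""
    return study_data.study_source_groups()


@pytest.fixture(scope="session")
def model0_tefs(study_groups):
    return build_tef_set("model0", study_groups)


@pytest.fixture(scope="session")
def study_composition():
    return study_data.study_diet_composition()


@pytest.fixture()
def rng():
    return np.random.default_rng(20180627)
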