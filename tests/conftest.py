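import numpy as np
import pytest

from qicar import load_study_properties, study_shaped_null


@pytest.fixture(scope="session")
def study_props():
    return load_study_properties()


@pytest.fixture(scope="session")
def null_data():
    """Study-shaped roster and availability with no planted dependence."""
    return study_shaped_null(7)


@pytest.fixture
def rng():
    return np.random.default_rng(20130305)
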