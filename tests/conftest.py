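import numpy as np
import pytest
from hypothesis import settings

from lohscan import load_default_panel, load_reference_cohort

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def reference():
    """Packaged 50-patient reference call matrix + grouping rules."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def reference_matrix(reference):
    return reference[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
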