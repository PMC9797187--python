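import numpy as np
import pytest

from huecat import probes as pr

#: unevenly spaced planted category borders used across the suite
PLANTED = np.array([0.03, 0.16, 0.30, 0.45, 0.60, 0.75, 0.90])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_borders():
    return PLANTED.copy()


@pytest.fixture(scope="session")
def scratch_backbone():
    """One small category-trained network shared by the slower tests."""
    return pr.make_scratch_category_backbone(PLANTED, seed=1)
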