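import numpy as np
import pytest

from remcycle.synthetic import default_ground_truth


@pytest.fixture(scope="session")
def gt():
    """The standard light-phase-like synthetic ground truth."""
    return default_ground_truth()


@pytest.fixture(scope="session")
def model(gt):
    return gt.model


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
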