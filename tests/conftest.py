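import numpy as np
import pytest

from pentadraw.geometry import IDEAL_SPEC
from pentadraw.simulator import generate


@pytest.fixture(scope="session")
def ideal_render():
    """One rendered ideal-spec drawing with its ground truth."""
    return generate(IDEAL_SPEC)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
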