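import numpy as np
import pytest
from hypothesis import settings

import tmaboost as tb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_slide():
    """One default-geometry synthetic slide with ground truth (seed 0)."""
    return tb.generate_slide(tb.TmaSpec(seed=0))


@pytest.fixture(scope="session")
def small_slide():
    """A small 2x3-core slide for fast per-core tests."""
    return tb.generate_slide(tb.TmaSpec(rows=2, cols=3, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
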