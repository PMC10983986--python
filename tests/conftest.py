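import numpy as np
import pytest

from lsgi.synthetic import make_default_slide


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_slide():
    """The reference synthetic slide, loadings only (no count simulation)."""
    return make_default_slide(seed=0, with_counts=False)


@pytest.fixture(scope="session")
def default_slide_counts():
    """The reference synthetic slide including Poisson counts."""
    return make_default_slide(seed=1)
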