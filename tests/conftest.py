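import numpy as np
import pytest

from wavehar import make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """Reduced synthetic benchmark shared by read-only tests (6 x 30)."""
    return make_benchmark(7, n_segments_per_class=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
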