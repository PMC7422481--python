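import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_instance(rng, max_n=40, max_d=8, max_c=4):
    """A random small classification instance with every class present."""
    C = int(rng.integers(2, max_c + 1))
    d = int(rng.integers(2, max_d + 1))
    N = int(rng.integers(C * 2, max_n + 1))
    X = rng.standard_normal((N, d))
    labels = np.concatenate([np.arange(C), rng.integers(0, C, size=N - C)])
    rng.shuffle(labels)
    return X, labels
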