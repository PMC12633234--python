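import numpy as np
import pytest


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation between two arrays (test-side oracle)."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_rotation(rng):
    from cryosim import Rotation

    def make():
        return Rotation(rng.normal(size=4))

    return make
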