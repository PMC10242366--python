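import numpy as np
import pytest

from spineseg.core_io import LabelMask, ScoreMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_scoremap(rng, h, w, k):
    """Uniformly random normalized score map."""
    raw = rng.random((h, w, k)) + 1e-3
    return ScoreMap((raw / raw.sum(axis=2, keepdims=True)).astype(np.float64))


def random_labelmask(rng, h, w, k):
    return LabelMask(rng.integers(0, k, size=(h, w)).astype(np.int32), k)


@pytest.fixture
def make_scoremap(rng):
    return lambda h=16, w=16, k=12: random_scoremap(rng, h, w, k)


@pytest.fixture
def make_labelmask(rng):
    return lambda h=16, w=16, k=12: random_labelmask(rng, h, w, k)
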