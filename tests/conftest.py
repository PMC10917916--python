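import numpy as np
import pytest

from mammofuse.synthetic import generate_images, generate_selection_benchmark


@pytest.fixture(scope="session")
def small_images():
    """Well-separated two-class phantoms at the generator's minimum size."""
    return generate_images(20, (64, 64), effect=0.9, seed=5)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small selection benchmark for fast wrapper tests."""
    return generate_selection_benchmark(60, 3, 7, seed=4, shift=2.0)


class StubRng:
    """Deterministic stand-in for numpy Generator: returns queued values."""

    def __init__(self, uniforms=(), normals=(), choices=()):
        self._uniforms = list(uniforms)
        self._normals = list(normals)
        self._choices = list(choices)

    def random(self):
        return self._uniforms.pop(0)

    def uniform(self, lo=0.0, hi=1.0):
        return self._uniforms.pop(0)

    def normal(self, *a, **k):
        return self._normals.pop(0)

    def choice(self, seq, size=None, replace=True):
        out = self._choices.pop(0)
        return np.asarray(out)


@pytest.fixture
def stub_rng():
    return StubRng
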