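import numpy as np
import pytest

from mammodensity import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def phantom_factory():
    """Factory for phantoms with sensible test defaults."""

    def make(**kwargs):
        kwargs.setdefault("rows", 128)
        kwargs.setdefault("cols", 128)
        kwargs.setdefault("seed", 7)
        return generate_phantom(PhantomSpec(**kwargs))

    return make


@pytest.fixture
def simple_phantom(phantom_factory):
    """A clean separable phantom: no noise, no falloff, no labels."""
    return phantom_factory(true_dense_fraction=0.25)
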