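import numpy as np
import pytest

from cartosom import ExpressionMatrix, make_gaussians


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """A 3x2 labelled matrix for loader/normalizer unit tests."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["a", "b"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture(scope="session")
def gauss_small():
    """Four tight blobs, 30 points each: cheap end-to-end fixture."""
    return make_gaussians(k=4, n=30, sd=0.4, separation=10.0, seed=7)


@pytest.fixture(scope="session")
def gauss_default():
    """The standard four-blob benchmark (400 points)."""
    return make_gaussians(seed=11)
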