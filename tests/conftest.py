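import numpy as np
import pytest

from mtbvs.bvs import residualize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_regression(n, p, q, effects=None, seed=0, noise_sd=1.0):
    """Small synthetic multivariate regression with known coefficients.

    ``effects`` maps predictor index -> array of q standardized effects.
    Returns residualized/standardized (Yt, Xt) plus the raw pieces.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    B = np.zeros((p, q))
    if effects:
        for j, row in effects.items():
            B[j] = row
    Y = X @ B + noise_sd * rng.standard_normal((n, q))
    C = np.ones((n, 1))
    Yt, Xt = residualize(Y, X, C)
    return Yt, Xt, B


@pytest.fixture
def small_regression():
    return make_regression(50, 6, 2, effects={0: [0.7, 0.0], 1: [0.0, 0.5]}, seed=0)
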