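import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("deterministic")

from ccpredict.expression_io import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 probes x 2 samples with simple values."""
    return ExpressionMatrix(
        ["p1", "p2", "p3"], ["s1", "s2"],
        np.array([[1.0, 2.0], [30.5, 40.25], [0.0, 7.0]]),
    )


def separable_data(n_pos=6, n_neg=7, n_features=4, gap=10.0, noise=0.3, seed=0):
    """Two well-separated Gaussian clouds, samples-by-features."""
    rng = np.random.default_rng(seed)
    Xp = rng.normal(gap, noise, size=(n_pos, n_features))
    Xn = rng.normal(0.0, noise, size=(n_neg, n_features))
    X = np.vstack([Xp, Xn])
    y = np.array([True] * n_pos + [False] * n_neg)
    return X, y
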