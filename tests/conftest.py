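import numpy as np
import pytest

from hoinfo import CorrelationMatrix


def random_correlation(n: int, rng: np.random.Generator, extra_dims: int = 5) -> CorrelationMatrix:
    """Random well-conditioned PD correlation matrix via a Wishart-style draw."""
    a = rng.standard_normal((n, n + extra_dims))
    s = a @ a.T
    d = np.sqrt(np.diag(s))
    s = s / np.outer(d, d)
    np.fill_diagonal(s, 1.0)
    return CorrelationMatrix(s)


def equicorrelated(n: int, rho: float) -> CorrelationMatrix:
    vals = np.full((n, n), rho)
    np.fill_diagonal(vals, 1.0)
    return CorrelationMatrix(vals)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
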