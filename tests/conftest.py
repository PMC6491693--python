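import numpy as np
import pytest

from latentscale import (
    CFAModel,
    ErrorCovariance,
    FactorLoadings,
    LatentCovariance,
)


def random_diagonal_model(rng, p=None, q=None, loading_range=(-1.0, 1.5)):
    """Random CFA model with diagonal Phi (positive variances)."""
    p = p or int(rng.integers(2, 13))
    q = q or int(rng.integers(1, 4))
    lam = rng.uniform(*loading_range, size=(p, q))
    phi = np.diag(rng.uniform(0.2, 2.0, size=q))
    theta = rng.uniform(0.2, 1.0, size=p)
    return CFAModel(
        loadings=FactorLoadings(lam),
        latent_cov=LatentCovariance(phi),
        error_cov=ErrorCovariance(theta),
    )


def random_positive_model(rng, p=None, q=None, correlated=False):
    """Random model with strictly positive loadings (valid for every scaling method)."""
    p = p or int(rng.integers(2, 13))
    q = q or int(rng.integers(1, 4))
    lam = rng.uniform(0.2, 1.2, size=(p, q))
    if correlated and q > 1:
        a = rng.uniform(-0.5, 0.5, size=(q, q))
        phi = a @ a.T + np.diag(rng.uniform(0.5, 1.5, size=q))
    else:
        phi = np.diag(rng.uniform(0.2, 2.0, size=q))
    theta = rng.uniform(0.2, 1.0, size=p)
    return CFAModel(
        loadings=FactorLoadings(lam),
        latent_cov=LatentCovariance(phi),
        error_cov=ErrorCovariance(theta),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
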