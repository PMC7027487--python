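import numpy as np
import pytest
from hypothesis import settings

from spjsdm.core import ParameterState
from spjsdm.data import CommunityData

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_community(rng):
    """12 sites, 3 species, 2 covariates, continuous responses."""
    n, n_s = 12, 3
    S = rng.uniform(0.0, 1.0, size=(n, 2))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    Y = rng.standard_normal((n, n_s))
    return CommunityData(Y=Y, X=X, S=S)


def random_state(data, n_f, rng, sigma2=None):
    """A consistent ParameterState with random parameters."""
    n, n_s = data.Y.shape
    n_c, n_t = data.n_covariates, data.n_traits
    return ParameterState(
        Z=data.Y.copy(),
        beta=rng.standard_normal((n_c, n_s)),
        gamma=rng.standard_normal((n_c, n_t)),
        lam=rng.standard_normal((n_f, n_s)),
        eta=rng.standard_normal((n, n_f)),
        alpha_index=np.zeros(n_f, dtype=int),
        phi=np.ones((n_f, n_s)),
        delta=np.ones(n_f),
        sigma2=np.ones(n_s) if sigma2 is None else np.asarray(sigma2, dtype=float),
    )
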