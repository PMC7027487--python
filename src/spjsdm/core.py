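"""Model definition: latent linear predictor, observation layer, priors.

The joint species distribution model couples a multivariate regression
with a low-rank, spatially structured residual.  For site ``i`` and
species ``j`` the latent variable is

    L_ij = sum_k x_ik beta_kj + sum_h eta_ih lambda_hj,

where ``eta`` holds ``n_f`` site-level latent factors and ``lambda``
their species loadings.  Presence-absence species observe
``y_ij ~ Bernoulli(Phi(L_ij))`` (probit link via a latent Gaussian
``Z_ij`` with unit variance); Gaussian species observe
``y_ij ~ N(L_ij, sigma_j^2)``.  The residual species-to-species
covariance is ``Omega = Lambda^T Lambda`` and its correlation scaling
``Omega*`` is the species association matrix.

Loadings carry the multiplicative-gamma increasing-shrinkage prior
(local precisions ``phi_hj`` and global factor precisions
``tau_h = prod_{l<=h} delta_l``), which orders factors by decreasing
importance and makes a fixed truncation ``n_f`` safe in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .data import CommunityData

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "ParameterState",
    "AssociationMatrices",
    "linear_predictor",
    "occurrence_probability",
    "association_matrix",
]

BERNOULLI = "bernoulli_probit"
GAUSSIAN = "gaussian_identity"
SPATIAL_METHODS = ("none", "gp", "gpp", "nngp")


@dataclass
class ModelSpec:
    """Structural choices: observation models, factor count, spatial backend.

    Parameters
    ----------
    observation_model : str or sequence of str
        ``"bernoulli_probit"`` or ``"gaussian_identity"``, either one value
        for all species or one per species.
    n_f : int
        Number of latent factors (fixed truncation, >= 1).
    spatial_method : {"none", "gp", "gpp", "nngp"}
        Prior on each factor over sites: independent standard normals,
        exact Gaussian process, knot-based predictive process, or
        nearest-neighbour Gaussian process.
    m : int
        Knot count target (gpp) or neighbour count (nngp); ignored otherwise.
    alpha_grid : 1-D array
        Candidate spatial ranges (distance units) for the exponential
        kernel; the value 0 denotes a nonspatial (white) factor.  The
        range is sampled over this grid during fitting.
    alpha_weights : 1-D array
        Prior weights over ``alpha_grid`` (sum to 1).
    """

    observation_model: object = BERNOULLI
    n_f: int = 2
    spatial_method: str = "nngp"
    m: int = 10
    alpha_grid: np.ndarray | None = None
    alpha_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_f < 1:
            raise ValueError("n_f must be >= 1")
        if self.spatial_method not in SPATIAL_METHODS:
            raise ValueError(f"spatial_method must be one of {SPATIAL_METHODS}")
        if self.spatial_method in ("gpp", "nngp") and self.m < 1:
            raise ValueError("m must be >= 1 for gpp/nngp")
        if self.alpha_grid is not None:
            self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
            if (self.alpha_grid < 0).any():
                raise ValueError("alpha_grid values must be >= 0")
            if self.alpha_weights is None:
                self.alpha_weights = np.full(
                    self.alpha_grid.size, 1.0 / self.alpha_grid.size
                )
            self.alpha_weights = np.asarray(self.alpha_weights, dtype=float)
            if self.alpha_weights.shape != self.alpha_grid.shape:
                raise ValueError("alpha_weights shape mismatch")
            if abs(self.alpha_weights.sum() - 1.0) > 1e-8:
                raise ValueError("alpha_weights must sum to 1")

    def observation_models(self, n_species: int) -> list[str]:
        om = self.observation_model
        if isinstance(om, str):
            models = [om] * n_species
        else:
            models = list(om)
            if len(models) != n_species:
                raise ValueError(
                    f"{len(models)} observation models for {n_species} species"
                )
        for m_ in models:
            if m_ not in (BERNOULLI, GAUSSIAN):
                raise ValueError(f"unknown observation model {m_!r}")
        return models

    def default_alpha_grid(self, S: np.ndarray, n_candidates: int = 20):
        """0 plus ``n_candidates`` log-spaced ranges up to the site diameter.

        Spans 0.01 x D_max to 1.0 x D_max (D_max = largest inter-site
        distance), covering sub-plot to full-extent correlation scales;
        prior weights uniform.
        """
        from scipy.spatial.distance import pdist

        d_max = float(pdist(S).max()) if S.shape[0] > 1 else 1.0
        grid = np.concatenate(
            [[0.0], np.geomspace(0.01 * d_max, d_max, n_candidates)]
        )
        self.alpha_grid = grid
        self.alpha_weights = np.full(grid.size, 1.0 / grid.size)
        return self


@dataclass
class PriorSpec:
    """Hyperparameters of all conjugate priors.

    beta rows are drawn around their trait-predicted mean,
    ``beta_.j ~ N(Gamma t_j, V0)``, with ``vec(Gamma) ~ N(0, gamma_var I)``.
    Gaussian species have ``sigma_j^2 ~ InvGamma(sigma2_shape, sigma2_rate)``
    (probit species keep sigma^2 = 1 for scale identifiability).  The
    loading shrinkage uses ``phi_hj ~ Gamma(nu/2, nu/2)`` locally and
    ``delta_1 ~ Gamma(a1, b1)``, ``delta_l ~ Gamma(a2, b2)`` (l > 1)
    multiplicatively; the defaults a2 > 1 give E[delta] > 1, i.e. an
    increasing-shrinkage regime across factors.
    """

    beta_cov: np.ndarray | float = 1.0       # V0, scalar -> V0 * I
    gamma_var: float = 1.0                   # prior variance of vec(Gamma)
    sigma2_shape: float = 1.0
    sigma2_rate: float = 1.0
    nu: float = 3.0
    a1: float = 5.0
    b1: float = 1.0
    a2: float = 5.0
    b2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_var", "sigma2_shape", "sigma2_rate",
                     "nu", "a1", "b1", "a2", "b2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def beta_cov_matrix(self, n_c: int) -> np.ndarray:
        V0 = self.beta_cov
        if np.isscalar(V0):
            return float(V0) * np.eye(n_c)
        V0 = np.asarray(V0, dtype=float)
        if V0.shape != (n_c, n_c):
            raise ValueError(f"beta_cov must be ({n_c}, {n_c})")
        if not np.allclose(V0, V0.T):
            raise ValueError("beta_cov must be symmetric")
        # positive-definiteness check via Cholesky
        np.linalg.cholesky(V0)
        return V0


@dataclass
class ParameterState:
    """One Gibbs state of all model unknowns."""

    Z: np.ndarray          # (n_y, n_s) latent Gaussian responses
    beta: np.ndarray       # (n_c, n_s)
    gamma: np.ndarray      # (n_c, n_t) trait coefficients
    lam: np.ndarray        # (n_f, n_s) factor loadings
    eta: np.ndarray        # (n_y, n_f) latent factors
    alpha_index: np.ndarray  # (n_f,) int indices into alpha_grid
    phi: np.ndarray        # (n_f, n_s) local shrinkage precisions
    delta: np.ndarray      # (n_f,) multiplicative shrinkage increments
    sigma2: np.ndarray     # (n_s,) residual variances (1 for probit species)

    @property
    def tau(self) -> np.ndarray:
        """Factor-level precisions tau_h = prod_{l<=h} delta_l."""
        return np.cumprod(self.delta)

    def copy(self) -> "ParameterState":
        return ParameterState(
            **{k: np.array(v, copy=True) for k, v in self.__dict__.items()}
        )


def linear_predictor(state: ParameterState, data: CommunityData) -> np.ndarray:
    """Latent linear predictor ``L = X beta + eta Lambda`` (site x species)."""
    X, beta, eta, lam = data.X, state.beta, state.eta, state.lam
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} covariates but beta has {beta.shape[0]} rows"
        )
    if eta.shape[1] != lam.shape[0]:
        raise ValueError(
            f"eta has {eta.shape[1]} factors but lambda has {lam.shape[0]} rows"
        )
    if eta.shape[0] != X.shape[0]:
        raise ValueError("eta and X disagree on the number of sites")
    return X @ beta + eta @ lam


def occurrence_probability(L) -> np.ndarray:
    """Probit occurrence probability ``Phi(L)`` (standard-normal CDF)."""
    return ndtr(np.asarray(L, dtype=float))


@dataclass
class AssociationMatrices:
    """Residual covariance ``Omega = Lambda^T Lambda`` and its correlation.

    ``defined[j, k]`` is False where the correlation scaling is undefined
    because species j or k has an all-zero loading column (zero variance);
    the corresponding ``omega_star`` entries are NaN.
    """

    omega: np.ndarray
    omega_star: np.ndarray
    defined: np.ndarray


def association_matrix(lam: np.ndarray) -> AssociationMatrices:
    """Species-to-species residual covariance and association (correlation).

    ``Omega = Lambda^T Lambda`` is symmetric positive semidefinite by
    construction; ``Omega*_jk = Omega_jk / sqrt(Omega_jj Omega_kk)``
    rescales it to the correlation form used to read species
    co-occurrence beyond what covariates explain.
    """
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    omega = lam.T @ lam
    d = np.diag(omega)
    ok = d > 0
    defined = np.outer(ok, ok)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt(np.outer(d, d))
        omega_star = np.where(defined, omega / np.where(scale > 0, scale, 1.0), np.nan)
    return AssociationMatrices(omega=omega, omega_star=omega_star, defined=defined)
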