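"""Posterior prediction at new sites and association inference.

New-site occurrence probabilities integrate over every source of
posterior uncertainty: for each retained draw the latent factors at the
new sites are *sampled* from their backend-specific conditional given
the training-site factors (not set to the conditional mean), then
``p = Phi(X0 beta + eta0 Lambda)`` is averaged across draws.

Backend conditionals:

* ``gp`` — exact joint Gaussian conditional (kriging) given training
  factors.
* ``gpp`` — the knot values implied by the draw are sampled from their
  Gaussian posterior given the training factors, projected to the new
  sites, and perturbed with the variance-correction noise so the
  predictive marginal prior variance stays 1.
* ``nngp`` — each new site conditions on its m nearest training sites
  (kernel kriging), independently per site; this yields the fine-scaled,
  possibly discontinuous prediction surfaces characteristic of the
  method.
* nonspatial factors — independent standard normal draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.spatial import cKDTree

from .core import association_matrix, occurrence_probability
from .sampler import PosteriorSamples
from .spatial import JITTER, KnotSet, build_knot_grid, exp_cov_matrix

__all__ = [
    "FactorPredictor",
    "PredictionResult",
    "AssociationSupport",
    "predict_probabilities",
    "predict_richness",
    "association_support",
]


@dataclass
class PredictionResult:
    """Posterior-mean probabilities and expected richness at new sites."""

    probabilities: np.ndarray           # (n0, n_s) across-draw mean Phi(L0)
    richness: np.ndarray                # (n0,) expected species count
    draw_probabilities: np.ndarray | None = None  # (n_draws, n0, n_s)


class FactorPredictor:
    """Samples latent factors at new sites, conditional on a posterior draw.

    Per-candidate-range projection weights depend only on the range and
    the new-site geometry, so they are cached and reused across draws.
    """

    def __init__(
        self,
        S_train: np.ndarray,
        S_new: np.ndarray,
        method: str,
        alpha_grid: np.ndarray,
        *,
        m: int = 10,
        knots: KnotSet | None = None,
    ):
        self.S = np.atleast_2d(np.asarray(S_train, dtype=float))
        self.S0 = np.atleast_2d(np.asarray(S_new, dtype=float))
        if not np.isfinite(self.S0).all():
            raise ValueError("new-site coordinates must be finite")
        self.method = method
        self.alpha_grid = np.asarray(alpha_grid, dtype=float)
        self.m = m
        if method == "gpp":
            self.knots = knots if knots is not None else build_knot_grid(self.S, m)
        if method == "nngp":
            k = min(m, self.S.shape[0])
            _, self._nn = cKDTree(self.S).query(self.S0, k=k)
            self._nn = np.atleast_2d(self._nn.reshape(self.S0.shape[0], k))
        self._cache: dict[int, tuple] = {}

    # -- per-range caches ---------------------------------------------------

    def _gp_cache(self, alpha):
        K = exp_cov_matrix(self.S, alpha=alpha)
        K[np.diag_indices_from(K)] += JITTER
        Kc = cho_factor(K, lower=True)
        K0S = exp_cov_matrix(self.S0, self.S, alpha=alpha)
        W = cho_solve(Kc, K0S.T).T               # K_{0S} K_SS^{-1}
        C = exp_cov_matrix(self.S0, alpha=alpha) - W @ K0S.T
        C[np.diag_indices_from(C)] += JITTER
        return W, cholesky(C, lower=True)

    def _gpp_cache(self, alpha):
        Sk = self.knots.coords
        Kkk = exp_cov_matrix(Sk, alpha=alpha)
        Kkk[np.diag_indices_from(Kkk)] += JITTER
        Kc = cho_factor(Kkk, lower=True)
        A = cho_solve(Kc, exp_cov_matrix(self.S, Sk, alpha=alpha).T).T  # (n, m)
        c = np.maximum(
            1.0 - np.einsum("ij,ji->i", A, exp_cov_matrix(Sk, self.S, alpha=alpha)),
            JITTER,
        )
        Q = np.linalg.inv(Kkk) + A.T @ (A / c[:, None])
        Qc = cho_factor(Q, lower=True)
        B0 = cho_solve(Kc, exp_cov_matrix(self.S0, Sk, alpha=alpha).T).T
        c0 = np.maximum(
            1.0 - np.einsum("ij,ji->i", B0, exp_cov_matrix(Sk, self.S0, alpha=alpha)),
            0.0,
        )
        AtCinv = (A / c[:, None]).T
        return Qc, AtCinv, B0, np.sqrt(c0)

    def _nngp_cache(self, alpha):
        n0, k = self._nn.shape
        weights = np.empty((n0, k))
        sd = np.empty(n0)
        for i in range(n0):
            nb = self._nn[i]
            Knn = exp_cov_matrix(self.S[nb], alpha=alpha)
            Knn[np.diag_indices_from(Knn)] += JITTER
            kvec = exp_cov_matrix(self.S0[i][None, :], self.S[nb], alpha=alpha)[0]
            w = np.linalg.solve(Knn, kvec)
            weights[i] = w
            sd[i] = np.sqrt(max(1.0 + JITTER - float(w @ kvec), 0.0))
        return weights, sd

    def _get(self, idx):
        if idx not in self._cache:
            alpha = self.alpha_grid[idx]
            if alpha == 0.0:
                self._cache[idx] = ("iid",)
            elif self.method == "gp":
                self._cache[idx] = ("gp", *self._gp_cache(alpha))
            elif self.method == "gpp":
                self._cache[idx] = ("gpp", *self._gpp_cache(alpha))
            elif self.method == "nngp":
                self._cache[idx] = ("nngp", *self._nngp_cache(alpha))
            else:
                self._cache[idx] = ("iid",)
        return self._cache[idx]

    # -- sampling -----------------------------------------------------------

    def sample(self, eta_draw: np.ndarray, alpha_index: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """One draw of the factors at the new sites, (n0, n_f)."""
        n0 = self.S0.shape[0]
        n_f = eta_draw.shape[1]
        out = np.empty((n0, n_f))
        for h in range(n_f):
            entry = self._get(int(alpha_index[h]))
            kind = entry[0]
            w = eta_draw[:, h]
            if kind == "iid":
                out[:, h] = rng.standard_normal(n0)
            elif kind == "gp":
                _, W, Lc = entry
                out[:, h] = W @ w + Lc @ rng.standard_normal(n0)
            elif kind == "gpp":
                _, Qc, AtCinv, B0, sd0 = entry
                mean_w = cho_solve(Qc, AtCinv @ w)
                wstar = mean_w + solve_triangular(
                    Qc[0], rng.standard_normal(len(mean_w)), lower=True, trans="T"
                )
                out[:, h] = B0 @ wstar + sd0 * rng.standard_normal(n0)
            else:  # nngp
                _, weights, sd = entry
                mean = np.einsum("ik,ik->i", weights, w[self._nn])
                out[:, h] = mean + sd * rng.standard_normal(n0)
        return out


def predict_probabilities(
    samples: PosteriorSamples,
    S_train: np.ndarray,
    S_new: np.ndarray,
    X_new: np.ndarray,
    *,
    seed: int = 0,
    knots: KnotSet | None = None,
    return_draws: bool = False,
) -> PredictionResult:
    """Posterior-mean occurrence probabilities at new sites.

    For each retained draw: sample new-site factors, form
    ``L0 = X0 beta + eta0 Lambda`` and ``p = Phi(L0)``; return the
    across-draw mean (optionally the per-draw array).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    n_c = samples.beta.shape[1]
    if X_new.shape[1] != n_c:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns but the fitted design has {n_c}"
        )
    if X_new.shape[0] != np.atleast_2d(S_new).shape[0]:
        raise ValueError("S_new and X_new must be row-aligned")
    rng = np.random.default_rng(seed)
    pred = FactorPredictor(
        S_train, S_new, samples.meta["spatial_method"], samples.alpha_grid,
        m=samples.meta.get("m", 10), knots=knots,
    )
    n0, n_s = X_new.shape[0], samples.beta.shape[2]
    acc = np.zeros((n0, n_s))
    draws = np.empty((samples.n_draws, n0, n_s)) if return_draws else None
    for d in range(samples.n_draws):
        eta0 = pred.sample(samples.eta[d], samples.alpha_index[d], rng)
        p = occurrence_probability(X_new @ samples.beta[d] + eta0 @ samples.lam[d])
        acc += p
        if return_draws:
            draws[d] = p
    probs = acc / samples.n_draws
    return PredictionResult(
        probabilities=probs,
        richness=predict_richness(probs),
        draw_probabilities=draws,
    )


def predict_richness(prob: np.ndarray) -> np.ndarray:
    """Expected species richness per site: the row sums of probabilities."""
    prob = np.atleast_2d(np.asarray(prob, dtype=float))
    if (prob < 0).any() or (prob > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return prob.sum(axis=1)


@dataclass
class AssociationSupport:
    """Posterior mean association matrix with a credibility mask.

    ``support[j, k]`` is True when the posterior sign of the association
    is consistent at the requested level (fraction of draws positive
    >= level or <= 1 - level); non-credible pairs should be displayed
    neutrally.
    """

    mean_omega_star: np.ndarray
    support: np.ndarray
    frac_positive: np.ndarray
    level: float


def association_support(samples: PosteriorSamples, level: float = 0.95
                        ) -> AssociationSupport:
    """Credible-sign filtering of the species association matrix."""
    if not (0.5 < level < 1.0):
        raise ValueError(f"credibility level must be in (0.5, 1), got {level}")
    if samples.n_draws < 2:
        raise ValueError("need at least 2 retained draws")
    n_s = samples.lam.shape[2]
    acc = np.zeros((n_s, n_s))
    pos = np.zeros((n_s, n_s))
    for d in range(samples.n_draws):
        assoc = association_matrix(samples.lam[d])
        acc += np.where(assoc.defined, assoc.omega_star, 0.0)
        pos += assoc.omega > 0
    frac = pos / samples.n_draws
    support = (frac >= level) | (frac <= 1.0 - level)
    return AssociationSupport(
        mean_omega_star=acc / samples.n_draws,
        support=support,
        frac_positive=frac,
        level=level,
    )
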