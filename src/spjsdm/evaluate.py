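"""Predictive accuracy metrics and MCMC diagnostics.

Out-of-sample accuracy for presence-absence species uses Tjur's R^2
(the mean predicted probability at presences minus the mean at
absences, the discrimination coefficient) and the Bernoulli deviance of
the posterior-mean probabilities.  Chain quality is summarized with the
autocorrelation-adjusted effective sample size and the Gelman-Rubin
potential scale reduction factor across independently initialized
chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "tjur_r2",
    "bernoulli_deviance",
    "effective_sample_size",
    "psrf",
    "EvaluationReport",
    "evaluate_predictions",
]

_EPS = 1e-12


def _check_binary_probs(y, p):
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError("y and p must have the same length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p must lie in [0, 1]")
    return y, p


def tjur_r2(y, p) -> float:
    """Tjur's discrimination coefficient: mean(p | y=1) - mean(p | y=0).

    Undefined (NaN) when only one class is observed; callers exclude such
    species from community averages rather than raising.
    """
    y, p = _check_binary_probs(y, p)
    pres = y == 1.0
    if pres.all() or (~pres).all():
        return float("nan")
    return float(p[pres].mean() - p[~pres].mean())


def bernoulli_deviance(y, p) -> float:
    """-2 x Bernoulli log-likelihood with probabilities clipped to
    [1e-12, 1 - 1e-12]."""
    y, p = _check_binary_probs(y, p)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def effective_sample_size(chain) -> float:
    """Autocorrelation-adjusted effective sample size of one chain.

    Uses ``n / (1 + 2 sum_k rho_k)`` with the autocorrelation sum
    truncated by the initial-monotone-positive-sequence rule on paired
    lags; the estimate is capped at n.  A zero-variance chain has no
    defined ESS and returns NaN.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws to estimate ESS")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return float("nan")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer pairs: Gamma_m = rho_{2m} + rho_{2m+1}, kept while positive
    # and forced monotone nonincreasing
    npair = n // 2
    gam = rho[0:2 * npair:2] + rho[1:2 * npair:2]
    pos = np.nonzero(gam <= 0)[0]
    if pos.size:
        gam = gam[: pos[0]]
    if gam.size == 0:
        return float(n)
    gam = np.minimum.accumulate(gam)
    tau = max(2.0 * gam.sum() - 1.0, 1e-12)
    return float(min(n / tau, n))


def psrf(chains) -> float:
    """Gelman-Rubin potential scale reduction factor across chains.

    sqrt(((n-1)/n W + B/n) / W) from the within- (W) and between-chain
    (B/n, variance of chain means) components.
    """
    chains = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(chains) < 2:
        raise ValueError("psrf requires at least 2 chains")
    n = chains[0].size
    if any(c.size != n for c in chains):
        raise ValueError("all chains must have equal length")
    if n < 2:
        raise ValueError("chains must have at least 2 draws")
    means = np.array([c.mean() for c in chains])
    W = float(np.mean([c.var(ddof=1) for c in chains]))
    B_over_n = float(means.var(ddof=1))
    if W == 0.0:
        return float("nan")
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


@dataclass
class EvaluationReport:
    """Per-species and community-level predictive metrics.

    Community means are unweighted over species with defined values;
    species undefined under Tjur's R^2 (single-class validation data)
    are reported as NaN and excluded from the mean.
    """

    tjur: np.ndarray
    deviance: np.ndarray
    species_names: list

    @property
    def mean_tjur(self) -> float:
        vals = self.tjur[np.isfinite(self.tjur)]
        return float(vals.mean()) if vals.size else float("nan")

    @property
    def mean_deviance(self) -> float:
        return float(np.mean(self.deviance))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {"tjur_r2": self.tjur, "deviance": self.deviance},
            index=self.species_names,
        )
        df.index.name = "species"
        return df


def evaluate_predictions(Y, P, species_names=None) -> EvaluationReport:
    """Per-species Tjur R^2 and deviance for a validation set."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if Y.shape != P.shape:
        raise ValueError("Y and P must have the same shape")
    n_s = Y.shape[1]
    names = list(species_names) if species_names else [f"sp{j}" for j in range(n_s)]
    tj = np.array([tjur_r2(Y[:, j], P[:, j]) for j in range(n_s)])
    dev = np.array([bernoulli_deviance(Y[:, j], P[:, j]) for j in range(n_s)])
    return EvaluationReport(tjur=tj, deviance=dev, species_names=names)
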