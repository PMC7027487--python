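"""Model and results objects: the package's high-level fitting surface.

Follows the familiar two-object pattern: :class:`SpatialFactorModel` is
constructed from data plus structural choices, and its :meth:`fit` runs
the Gibbs sampler and returns a :class:`SpatialFactorResults` carrying
the posterior draws, summaries, association inference, prediction and
out-of-sample evaluation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BERNOULLI, ModelSpec, PriorSpec
from .data import CommunityData
from .evaluate import (
    EvaluationReport,
    effective_sample_size,
    evaluate_predictions,
    psrf,
)
from .predict import (
    AssociationSupport,
    PredictionResult,
    association_support,
    predict_probabilities,
)
from .sampler import ChainConfig, PosteriorSamples, build_candidates, run_gibbs

__all__ = ["SpatialFactorModel", "SpatialFactorResults"]


class SpatialFactorModel:
    """Joint species distribution model with spatial latent factors.

    Parameters
    ----------
    Y, X, coords, traits : array-likes
        See :class:`~spjsdm.data.CommunityData`.
    observation : str or sequence
        Observation model(s): ``"bernoulli_probit"`` or
        ``"gaussian_identity"``.
    n_factors : int
        Latent factor count (fixed truncation).
    spatial : {"none", "gp", "gpp", "nngp"}
        Spatial prior backend for the factors.
    m : int
        Knot-count target (gpp) or neighbour count (nngp).
    alpha_grid, alpha_weights : arrays, optional
        Candidate spatial ranges and their prior weights; defaults to 0
        plus 20 log-spaced ranges up to the site diameter, uniform prior.
    priors : PriorSpec, optional
        Hyperparameters; defaults are weakly informative.

    Examples
    --------
    >>> model = SpatialFactorModel(Y, X, coords, spatial="nngp", m=10)
    >>> res = model.fit(n_iter=2000, n_burn=500, thin=5, seed=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        Y,
        X,
        coords,
        traits=None,
        *,
        observation=BERNOULLI,
        n_factors: int = 2,
        spatial: str = "nngp",
        m: int = 10,
        alpha_grid=None,
        alpha_weights=None,
        priors: PriorSpec | None = None,
        species_names=None,
        site_ids=None,
    ):
        self.data = CommunityData(
            Y=np.asarray(Y), X=np.asarray(X), S=np.asarray(coords),
            T=None if traits is None else np.asarray(traits),
            species_names=list(species_names) if species_names else [],
            site_ids=list(site_ids) if site_ids else [],
        )
        self.spec = ModelSpec(
            observation_model=observation,
            n_f=n_factors,
            spatial_method=spatial,
            m=m,
            alpha_grid=alpha_grid,
            alpha_weights=alpha_weights,
        )
        self.priors = priors or PriorSpec()
        models = self.spec.observation_models(self.data.n_species)
        probit_cols = np.array([mm == BERNOULLI for mm in models])
        if probit_cols.any():
            self.data.validate_bernoulli(np.where(probit_cols)[0])

    @classmethod
    def from_community(cls, data: CommunityData, **kwargs) -> "SpatialFactorModel":
        return cls(
            data.Y, data.X, data.S, data.T,
            species_names=data.species_names, site_ids=data.site_ids, **kwargs
        )

    @classmethod
    def from_dataframes(cls, Y: pd.DataFrame, X: pd.DataFrame,
                        coords: pd.DataFrame, traits: pd.DataFrame | None = None,
                        **kwargs) -> "SpatialFactorModel":
        """Build from index-aligned pandas tables (site order taken from Y)."""
        X = X.loc[Y.index]
        coords = coords.loc[Y.index]
        T = traits.loc[Y.columns].to_numpy() if traits is not None else None
        return cls(
            Y.to_numpy(), X.to_numpy(), coords[["x", "y"]].to_numpy(), T,
            species_names=[str(c) for c in Y.columns],
            site_ids=[str(i) for i in Y.index],
            **kwargs,
        )

    def fit(
        self,
        n_iter: int = 10_000,
        n_burn: int = 2_000,
        thin: int = 10,
        seed: int = 0,
        n_chains: int = 1,
        verbosity: int = 0,
        init: str = "default",
    ) -> "SpatialFactorResults":
        """Run the block Gibbs sampler.

        Parallel-chain seeds are derived as ``seed + chain`` so each chain
        is reproducible in isolation; candidate spatial structures are
        factorized once and shared across chains.
        """
        candidates = build_candidates(self.data, self.spec)
        chains = []
        for c in range(n_chains):
            cfg = ChainConfig(
                n_iter=n_iter, n_burn=n_burn, thin=thin,
                seed=seed + c, verbosity=verbosity,
            )
            chains.append(
                run_gibbs(self.data, self.spec, self.priors, cfg,
                          candidates=candidates,
                          init=init if c == 0 else "prior")
            )
        return SpatialFactorResults(self, chains, candidates)


class SpatialFactorResults:
    """Posterior draws plus inference utilities for a fitted model."""

    def __init__(self, model: SpatialFactorModel, chains, candidates):
        self.model = model
        self.chains = list(chains)
        self.samples: PosteriorSamples = self.chains[0]
        self._candidates = candidates

    # -- point estimates and intervals -------------------------------------

    @property
    def beta_mean(self) -> np.ndarray:
        return self.samples.beta.mean(axis=0)

    @property
    def sigma2_mean(self) -> np.ndarray:
        return self.samples.sigma2.mean(axis=0)

    def beta_interval(self, prob: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
        """Equal-tailed credible interval bounds for every beta entry."""
        lo = (1.0 - prob) / 2.0
        return (
            np.quantile(self.samples.beta, lo, axis=0),
            np.quantile(self.samples.beta, 1.0 - lo, axis=0),
        )

    def alpha_posterior(self) -> pd.DataFrame:
        """Posterior frequency of each candidate range, per factor."""
        grid = self.samples.alpha_grid
        n_f = self.samples.alpha_index.shape[1]
        rows = {}
        for h in range(n_f):
            counts = np.bincount(self.samples.alpha_index[:, h], minlength=len(grid))
            rows[f"factor{h + 1}"] = counts / counts.sum()
        return pd.DataFrame(rows, index=pd.Index(grid, name="alpha"))

    # -- association and prediction -----------------------------------------

    def association(self, level: float = 0.95) -> AssociationSupport:
        """Posterior mean association matrix with credible-sign mask."""
        return association_support(self.samples, level=level)

    def predict(self, coords_new, X_new, *, seed: int = 0,
                return_draws: bool = False) -> PredictionResult:
        """Posterior-mean occurrence probabilities and richness at new sites."""
        return predict_probabilities(
            self.samples, self.model.data.S, coords_new, X_new,
            seed=seed, knots=getattr(self._candidates, "knots", None),
            return_draws=return_draws,
        )

    def evaluate(self, Y_val, coords_val, X_val, *, seed: int = 0
                 ) -> EvaluationReport:
        """Out-of-sample Tjur R^2 and deviance on a validation set."""
        pred = self.predict(coords_val, X_val, seed=seed)
        return evaluate_predictions(
            Y_val, pred.probabilities, self.model.data.species_names
        )

    # -- diagnostics --------------------------------------------------------

    def ess(self) -> dict:
        """Effective sample sizes per parameter block, plus the minimum.

        Reported per scalar element of beta, lambda and sigma2 of the
        primary chain; the dictionary carries each block's array and the
        overall minimum (the mixing bottleneck).
        """
        s = self.samples
        blocks = {
            "beta": s.beta, "lambda": s.lam, "sigma2": s.sigma2[:, :, None],
        }
        out = {}
        mins = []
        for name, arr in blocks.items():
            flat = arr.reshape(arr.shape[0], -1)
            ess = np.array([
                effective_sample_size(flat[:, k]) for k in range(flat.shape[1])
            ])
            out[name] = ess.reshape(arr.shape[1:])
            vals = ess[np.isfinite(ess)]
            if vals.size:
                mins.append(vals.min())
        out["min"] = float(min(mins)) if mins else float("nan")
        return out

    def psrf_max(self) -> float:
        """Largest potential scale reduction over beta entries (multi-chain)."""
        if len(self.chains) < 2:
            raise ValueError("psrf requires at least 2 chains; refit with n_chains>=2")
        flat = [c.beta.reshape(c.beta.shape[0], -1) for c in self.chains]
        vals = [
            psrf([f[:, k] for f in flat]) for k in range(flat[0].shape[1])
        ]
        vals = [v for v in vals if np.isfinite(v)]
        return float(max(vals)) if vals else float("nan")

    # -- reporting ----------------------------------------------------------

    def summary(self, prob: float = 0.9) -> str:
        data, spec, s = self.model.data, self.model.spec, self.samples
        lo, hi = self.beta_interval(prob)
        bm = self.beta_mean
        lines = [
            "Spatial latent-factor JSDM results",
            "=" * 50,
            f"sites: {data.n_sites}   species: {data.n_species}   "
            f"covariates: {data.n_covariates}",
            f"spatial backend: {spec.spatial_method} (m={spec.m})   "
            f"factors: {spec.n_f}",
            f"retained draws: {s.n_draws}   "
            f"(n_iter={s.meta['n_iter']}, burn={s.meta['n_burn']}, "
            f"thin={s.meta['thin']}, seed={s.meta['seed']})",
            "",
            f"beta posterior means with {int(prob * 100)}% credible intervals:",
        ]
        for j, sp_name in enumerate(data.species_names):
            cells = [
                f"{bm[k, j]: .3f} [{lo[k, j]: .3f},{hi[k, j]: .3f}]"
                for k in range(data.n_covariates)
            ]
            lines.append(f"  {sp_name:<12}" + "  ".join(cells))
        ap = self.alpha_posterior()
        lines.append("")
        lines.append("posterior mode of the spatial range per factor:")
        for h, col in enumerate(ap.columns):
            mode_alpha = ap.index[np.argmax(ap[col].to_numpy())]
            lines.append(
                f"  factor {h + 1}: alpha = {mode_alpha:.4f} "
                f"(posterior mass {ap[col].max():.2f})"
            )
        return "\n".join(lines)

    def plot_associations(self, ax=None, level: float = 0.95):
        """Heat map of the credible-sign-filtered association matrix."""
        import matplotlib.pyplot as plt

        assoc = self.association(level=level)
        shown = np.where(assoc.support, assoc.mean_omega_star, 0.0)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(shown, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xlabel("species")
        ax.set_ylabel("species")
        ax.figure.colorbar(im, ax=ax, label="association")
        return ax
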