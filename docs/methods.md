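# Methods

`spjsdm` fits a hierarchical Bayesian joint species distribution model
(JSDM) in which residual dependence among species is carried by spatially
autocorrelated latent factors. This note records the model, the
numerical choices, the design decisions that were genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Model

For sites `i = 1..n_y` with coordinates `s_i` (planar Euclidean) and
species `j = 1..n_s`, the latent predictor is

    L_ij = sum_k x_ik beta_kj + sum_h eta_ih lambda_hj .

Observations are either presence-absence with a probit link,
`y_ij ~ Bernoulli(Phi(L_ij))`, represented through the latent Gaussian
`Z_ij ~ N(L_ij, 1)` whose sign matches `y_ij` (probit data
augmentation), or Gaussian, `y_ij ~ N(L_ij, sigma_j^2)`.

The residual `eps = eta Lambda` implies a species-to-species covariance
`Omega = Lambda^T Lambda`; its correlation scaling `Omega*` is the
association matrix: positive entries mark species pairs co-occurring
more than the covariates explain. With `n_f << n_s` this is a low-rank
representation of residual dependence (a linear model of
coregionalization once the factors are spatial).

Each factor column `eta_.h` has a zero-mean Gaussian-process prior with
exponential covariance `k(s, s') = exp(-||s - s'|| / alpha_h)`. The
kernel variance is fixed at 1 — the factor scale lives in the loadings —
and `alpha_h` (the distance at which correlation falls to 1/e) is
sampled over a discrete grid during fitting.

Priors: species coefficients `beta_.j ~ N(Gamma t_j, V0)` with trait
design `t_j` (an intercept when no traits are supplied, so `Gamma`
becomes a shared prior mean) and `vec(Gamma) ~ N(0, gamma_var I)`;
loadings carry the multiplicative-gamma increasing-shrinkage prior,
`lambda_hj ~ N(0, (phi_hj tau_h)^{-1})`, `phi_hj ~ Ga(nu/2, nu/2)`,
`tau_h = prod_{l<=h} delta_l`, `delta_1 ~ Ga(a1, b1)`,
`delta_l ~ Ga(a2, b2)`; Gaussian residual variances are
inverse-gamma; probit species have `sigma_j^2 = 1` fixed for scale
identifiability.

### Default hyperparameters

| parameter | default | why |
| --- | --- | --- |
| `nu` | 3 | heavy-tailed local shrinkage, standard for gamma-local scales |
| `a1, b1` | 5, 1 | first global increment centred well above 1 |
| `a2, b2` | 5, 1 | `E[delta] = 5 > 1`: precisions increase, factors ordered by importance |
| `V0` | identity | unit-scale coefficients on standardized covariates |
| `gamma_var` | 1 | weakly informative trait regression |
| `sigma2` shape/rate | 1, 1 | vague inverse-gamma for Gaussian species |
| `n_f` | 2 | fixed truncation; adaptive truncation is out of scope |
| alpha grid | 0 plus 20 log-spaced values in [0.01, 1] x max inter-site distance, uniform prior | covers sub-plot to full-extent ranges; 0 is the nonspatial factor |

All are configurable (`PriorSpec`, `ModelSpec`).

## Spatial backends

The factor-prior covariance over sites admits three factorizations.

**Exact GP (`gp`).** Dense covariance and Cholesky factor; O(n^3) per
candidate range, usable only for small `n`.

**Gaussian predictive process (`gpp`).** The field is summarized at `m`
knots placed on a uniform hexagonal lattice covering the site bounding
box (rows pitched `sqrt(3)/2 x` spacing, alternate rows offset half a
spacing; the spacing is the largest whose lattice holds at least the
requested number of nodes, so offset rows may extend slightly past the
box). Projecting onto the knot field gives the low-rank covariance
`U U^T` with `U = K_{S S*} chol(K_{S*S*})^{-T}`; the diagonal
correction `c_i = 1 - sum_t U_it^2` (the "modified" predictive process)
restores the exact unit prior variance at every site. Solves and
log-determinants use Woodbury / matrix-determinant-lemma identities on
the knot scale; no dense `n x n` matrix is formed.

**Nearest-neighbour GP (`nngp`).** Sites are ordered by first
coordinate (ties: second coordinate, then input index); each ordered
site conditions on its `m` nearest predecessors (ties prefer the
smaller ordered index), giving `K^ = (I-A)^{-1} D (I-A)^{-T}` with a
sparse unit-lower-triangular `I - A` (at most `n(m+1)` structural
nonzeros) and a sparse precision.

Numerical choices:

* A fixed jitter of `1e-8` is added to every dense covariance diagonal
  before factorization. The predictive process treats this jitter as a
  kernel nugget consistently — the site-knot cross-covariance carries
  the same nugget at zero distance — so its exact limit (knots = sites)
  reproduces the jittered dense covariance to machine precision rather
  than only to O(jitter x condition number).
* When the predictive-process correction `c` underflows (a site sitting
  on a knot, `min c <= 1e-6`), the Woodbury form is ill-posed and the
  structure falls back to a dense factorization. This occurs only in
  the degenerate knots~sites regime used by exactness checks, never in
  the `m << n` production regime.
* Both approximations are exact in their limits (knots = sites;
  `m >= n-1`); the tests use the dense GP as the oracle there.

## Block Gibbs sampler

One sweep updates, in order: `Z` (truncated normals), `beta`/`Gamma`,
`Lambda`, the shrinkage variables, `eta`, `alpha`, `sigma^2`. The order
is a residual-conditioning chain — each update sees the freshest
residuals; it is a design choice, not forced by the math.

All factors at all sites are updated in one block from the exact
Gaussian full conditional with precision
`P = blockdiag_h(K_h^{-1}) + (Lambda Sigma^{-1} Lambda^T) kron I_n`.
Rather than factorizing `P` into a square root for sampling, the
sampler uses an exact perturbation ("sample-then-solve") scheme: perturb
the right-hand side `b = vec(R Sigma^{-1} Lambda^T)` with a draw from
`N(0, P)` — assembled from per-factor `N(0, K_h^{-1})` draws plus the
likelihood term `vec(Z2 Sigma^{-1/2} Lambda^T)` with `Z2` standard
normal — and solve `P x = b + noise`. The result is an exact draw from
`N(P^{-1} b, P^{-1})`, and each backend only needs a linear solver for
`P`: site-wise `n_f x n_f` blocks (nonspatial), dense (full GP), sparse
LU (NNGP), or a knot-scale Woodbury reduction (GPP). Correctness is
checked against dense closed forms to 1e-6 for every backend.

The spatial ranges are updated per factor on the static grid with
probability proportional to prior weight times the Gaussian prior
density of the current factor column under each candidate covariance
(log-sum-exp stabilized). All candidate structures are factorized once
per fit; memory is the price of avoiding per-sweep refactorization.

Chains are fully reproducible: one seeded generator per chain, parallel
chains at `seed + chain index`; multi-chain fits can be initialized
from the prior for dispersion diagnostics (Gelman-Rubin).

## Prediction

Occurrence probabilities at new sites integrate over all posterior
uncertainty: for each retained draw the new-site factors are *sampled*
from their conditional given the training factors — exact joint kriging
(gp); sampling the knot field from its posterior given the training
factors, projecting, and adding the variance-correction noise (gpp);
kriging on the `m` nearest training sites independently per new site
(nngp; this deliberately reproduces the method's fine-scaled,
potentially discontinuous prediction surfaces and keeps prediction
embarrassingly parallel); standard normals (nonspatial) — then
`p = Phi(X0 beta + eta0 Lambda)` is averaged over draws. Expected
richness is the row sum of probabilities. Association support masks
species pairs whose posterior sign consistency falls below the
requested credibility level.

## Evaluation and diagnostics

Tjur's R^2 (mean predicted probability at presences minus absences) and
Bernoulli deviance of the posterior-mean probabilities, per species;
community values are unweighted means over species with defined values
(single-class validation species are reported as NaN and excluded).
Effective sample size uses the initial-monotone-positive-sequence
truncation of paired autocorrelations, capped at the chain length;
potential scale reduction is the standard between/within variance ratio.
ESS is reported per parameter block plus the overall minimum (the
mixing bottleneck).

## Synthetic data and what the benchmarks show

The generator draws coordinates (uniform square, clustered, or 1-D
transect), standard-normal covariates (optionally with squared copies
for peaked responses), factors from the *exact dense* GP at all sites
jointly, and responses from the assumed observation model; a uniform
random site split (default one-sixth) yields the validation set, and
every generating parameter is returned.

Default truths: `beta ~ N(0,1)`; loadings `lambda_hj ~ N(0, 1/h)` so
factor importance decreases and the residual field is comparable to a
covariate effect (loadings can also be drawn from the shrinkage prior
or passed explicitly); Gaussian noise variance 0.25 so the latent field
dominates observation noise; true range 0.12 x the extent — the regime
reported for real community data, where only nearby sites are
effectively non-independent.

Benchmarks at desk scale: recovery uses 400 training sites, 8 species,
2 factors, Gaussian observations, 1,500 sweeps (500 burn-in, thin 5);
the spatial-benefit comparison uses 800 training / 200 validation
sites, 20 species, presence-absence data with true range 0.3 x extent,
comparing nonspatial, coarse- and fine-knot predictive-process and
NNGP fits by validation Tjur R^2.

Because the generator matches the model family exactly, passing these
checks demonstrates the sampler and the spatial approximations are
correct *under the model's own assumptions*. They do not probe kernel
misspecification, anisotropy, unmeasured covariates, preferential
sampling, or observation error structure found in real surveys.

## Known limitations

* **Intercept / field-mean confounding.** When the true range is
  comparable to the study extent, each factor field has a large regional
  mean that the likelihood cannot separate from species intercepts. The
  joint posterior has a ridge, and the single-block Gibbs sampler
  traverses it by a small-step random walk, so intercept intervals can
  undercover at practical chain lengths even though slopes and
  associations are recovered essentially perfectly. Centred
  reparameterizations or interweaving would mitigate this but are out
  of scope.
* **Probit augmentation mixing.** The classic data-augmentation scheme
  mixes slowly as site counts grow; effective sample sizes per sweep
  drop accordingly. This cost is inherent to the scheme and is
  reported, not hidden, by the ESS diagnostics.
* Factor labels are not identified (rotation/sign); only rotation-
  invariant summaries (`Omega*`, predictions) should be interpreted.
* Coordinates are planar Euclidean; project geographic data first.
* The factor count is a fixed truncation chosen by the user; the
  shrinkage prior orders factors but no adaptive truncation is done.
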