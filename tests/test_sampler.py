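"""Conditional correctness of every Gibbs update, and chain mechanics.

Gaussian-conditional updates are checked two ways: a zero-noise
generator turns a draw into the exact conditional mean (compared with
closed forms at tight tolerance), and Monte Carlo moments over repeated
draws are compared with the analytic conditional at 3 standard errors.
"""

import numpy as np
import pytest
import scipy.linalg as sla
from scipy import stats

from spjsdm.core import ModelSpec, ParameterState, PriorSpec
from spjsdm.data import CommunityData
from spjsdm.sampler import (
    ChainConfig,
    CandidateStructures,
    make_eta_solver,
    run_gibbs,
    update_Z,
    update_alpha,
    update_beta_gamma,
    update_eta,
    update_lambda,
    update_shrinkage,
    update_sigma2,
)
from spjsdm.spatial import (
    IdentityStructure,
    KnotSet,
    build_knot_grid,
    build_neighbor_graph,
    build_structure,
    exp_cov_matrix,
)

from .conftest import random_state


class ZeroNormalRng:
    """Generator stand-in whose Gaussian noise is exactly zero.

    Feeding it to a Gaussian-conditional update makes the 'draw' equal
    the conditional mean, enabling deterministic oracle comparisons.
    """

    def standard_normal(self, size=None):
        return 0.0 if size is None else np.zeros(size)


class TestUpdateZ:
    def make(self, rng, L_value=0.0):
        n, n_s = 6, 2
        data = CommunityData(
            Y=(rng.uniform(size=(n, n_s)) < 0.5).astype(float),
            X=np.ones((n, 1)),
            S=rng.uniform(size=(n, 2)),
        )
        state = random_state(data, 1, rng)
        state.beta[:] = L_value
        state.lam[:] = 0.0
        return data, state

    def test_sign_agrees_with_response(self, rng):
        data, state = self.make(rng)
        for _ in range(50):
            update_Z(state, data, np.array([True, True]), rng)
            assert np.all((state.Z > 0) == (data.Y > 0.5))

    def test_half_normal_mean_at_zero_predictor(self, rng):
        # L = 0, Y = 1: Z is half-normal with mean sqrt(2/pi)
        n = 100_000
        data = CommunityData(
            Y=np.ones((n, 1)), X=np.ones((n, 1)), S=rng.uniform(size=(n, 2))
        )
        state = random_state(data, 1, rng)
        state.beta[:] = 0.0
        state.lam[:] = 0.0
        update_Z(state, data, np.array([True]), rng)
        target = np.sqrt(2.0 / np.pi)
        se = np.sqrt(1.0 - 2.0 / np.pi) / np.sqrt(n)
        assert state.Z.mean() == pytest.approx(target, abs=3 * se)

    def test_far_tail_is_finite(self, rng):
        data, state = self.make(rng, L_value=-10.0)
        data.Y[:] = 1.0
        update_Z(state, data, np.array([True, True]), rng)
        assert np.isfinite(state.Z).all()
        assert (state.Z > 0).all()

    def test_gaussian_species_untouched(self, rng):
        data, state = self.make(rng)
        z0 = state.Z.copy()
        update_Z(state, data, np.array([True, False]), rng)
        np.testing.assert_array_equal(state.Z[:, 1], z0[:, 1])


class TestUpdateBetaGamma:
    def test_conditional_mean_matches_gls_closed_form(self, rng):
        n, n_c = 30, 2
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = CommunityData(
            Y=rng.standard_normal((n, 1)), X=X, S=rng.uniform(size=(n, 2))
        )
        state = random_state(data, 1, rng)
        state.eta[:] = 0.0
        state.gamma[:] = 0.0
        sigma2 = 2.0
        state.sigma2[:] = sigma2
        priors = PriorSpec(beta_cov=1e8, gamma_var=1e-12)
        update_beta_gamma(state, data, priors, ZeroNormalRng())
        # flat prior limit: the conditional mean is the GLS/OLS estimate
        expected = np.linalg.solve(X.T @ X, X.T @ data.Y[:, 0])
        np.testing.assert_allclose(state.beta[:, 0], expected, atol=1e-6)

    def test_prior_domination_shrinks_to_prior_mean(self, rng):
        data = CommunityData(
            Y=rng.standard_normal((10, 2)),
            X=np.ones((10, 1)),
            S=rng.uniform(size=(10, 2)),
        )
        state = random_state(data, 1, rng)
        state.gamma[:] = 0.0
        priors = PriorSpec(beta_cov=1e-12, gamma_var=1e-12)
        update_beta_gamma(state, data, priors, rng)
        np.testing.assert_allclose(state.beta, 0.0, atol=1e-4)

    def test_likelihood_washout_reverts_to_prior(self, rng):
        # sigma^2 -> infinity: beta | Gamma ~ N(Gamma t, V0)
        data = CommunityData(
            Y=rng.standard_normal((8, 3)),
            X=np.column_stack([np.ones(8), rng.standard_normal(8)]),
            S=rng.uniform(size=(8, 2)),
        )
        priors = PriorSpec(beta_cov=1.0, gamma_var=1.0)
        state = random_state(data, 1, rng)
        state.eta[:] = 0.0
        state.sigma2[:] = 1e12
        n_rep = 4000
        resid = []
        for _ in range(n_rep):
            prior_mean = state.gamma @ data.T.T
            update_beta_gamma(state, data, priors, rng)
            resid.append((state.beta - prior_mean).ravel())
        resid = np.array(resid)
        se = 1.0 / np.sqrt(n_rep)
        assert np.abs(resid.mean(axis=0)).max() < 4 * se
        np.testing.assert_allclose(resid.var(axis=0), 1.0, atol=0.15)


class TestUpdateLambda:
    def test_scalar_conjugate_closed_form(self, rng):
        # n_f = 1, known eta, sigma^2 = 1: textbook 1-D conjugate posterior
        n = 25
        data = CommunityData(
            Y=rng.standard_normal((n, 1)),
            X=np.ones((n, 1)),
            S=rng.uniform(size=(n, 2)),
        )
        state = random_state(data, 1, rng)
        state.beta[:] = 0.0
        state.phi[:] = 2.0
        state.delta[:] = 1.5
        eta = state.eta[:, 0]
        prec = 2.0 * 1.5 + eta @ eta
        expected_mean = (eta @ data.Y[:, 0]) / prec
        update_lambda(state, data, ZeroNormalRng())
        assert state.lam[0, 0] == pytest.approx(expected_mean, abs=1e-10)
        # conditional sd via MC
        draws = []
        for _ in range(20_000):
            update_lambda(state, data, rng)
            draws.append(state.lam[0, 0])
        assert np.std(draws) == pytest.approx(1.0 / np.sqrt(prec), rel=0.05)

    def test_shrinkage_domination_zeroes_loadings(self, rng, small_community):
        state = random_state(small_community, 2, rng)
        state.phi[:] = 1e12
        update_lambda(state, small_community, rng)
        np.testing.assert_allclose(state.lam, 0.0, atol=1e-4)

    def test_no_information_reverts_to_prior(self, rng, small_community):
        state = random_state(small_community, 2, rng)
        state.eta[:] = 0.0
        state.phi[:] = 4.0
        state.delta[:] = 1.0
        draws = []
        for _ in range(20_000):
            update_lambda(state, small_community, rng)
            draws.append(state.lam.copy())
        draws = np.array(draws)
        np.testing.assert_allclose(draws.mean(axis=0), 0.0, atol=0.02)
        np.testing.assert_allclose(draws.var(axis=0), 0.25, atol=0.02)


class TestUpdateShrinkage:
    def test_zero_loadings_phi_prior_moments(self, rng, small_community):
        state = random_state(small_community, 2, rng)
        state.lam[:] = 0.0
        priors = PriorSpec()
        means = []
        for _ in range(5_000):
            update_shrinkage(state, priors, rng)
            means.append(state.phi.mean())
            assert (state.tau > 0).all()
            assert (state.phi > 0).all()
        # Lambda = 0: phi ~ Gamma((nu+1)/2, nu/2), mean (nu+1)/nu
        expected = (priors.nu + 1.0) / priors.nu
        assert np.mean(means) == pytest.approx(expected, rel=0.02)

    def test_single_factor_phi_density_by_quadrature(self, rng):
        # p(phi | lambda) prop. to Gamma(phi; nu/2, nu/2) N(lambda; 0, 1/(phi tau))
        data = CommunityData(
            Y=np.zeros((4, 1)), X=np.ones((4, 1)), S=rng.uniform(size=(4, 2))
        )
        state = random_state(data, 1, rng)
        lam_val, tau_val, nu = 1.7, 1.0, 3.0
        state.lam[:] = lam_val
        state.delta[:] = tau_val
        priors = PriorSpec(nu=nu)
        grid = np.linspace(1e-6, 40.0, 200_001)
        kern = stats.gamma.pdf(grid, nu / 2.0, scale=2.0 / nu) * stats.norm.pdf(
            lam_val, 0.0, 1.0 / np.sqrt(grid * tau_val)
        )
        kern /= np.trapezoid(kern, grid)
        expected_mean = np.trapezoid(grid * kern, grid)
        draws = []
        for _ in range(30_000):
            state.delta[:] = tau_val  # hold tau fixed at the oracle's value
            update_shrinkage(state, priors, rng)
            draws.append(state.phi[0, 0])
        se = np.std(draws) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(expected_mean, abs=4 * se)


class TestUpdateEta:
    @pytest.mark.parametrize("backend", ["none", "gp", "gpp", "gpp_exact", "nngp", "nngp_exact"])
    def test_conditional_matches_dense_closed_form(self, backend, rng):
        n, n_s, n_f = 12, 3, 2
        S = rng.uniform(size=(n, 2))
        data = CommunityData(
            Y=rng.standard_normal((n, n_s)),
            X=np.column_stack([np.ones(n), rng.standard_normal(n)]),
            S=S,
        )
        state = random_state(data, n_f, rng, sigma2=[0.5, 1.0, 2.0])
        alpha = 0.4
        structs = {
            "none": lambda: [IdentityStructure(n)] * n_f,
            "gp": lambda: [build_structure(S, "gp", alpha)] * n_f,
            "gpp": lambda: [
                build_structure(S, "gpp", alpha, knots=build_knot_grid(S, 5))
            ] * n_f,
            "gpp_exact": lambda: [
                build_structure(S, "gpp", alpha, knots=KnotSet(S.copy(), 0.1))
            ] * n_f,
            "nngp": lambda: [
                build_structure(S, "nngp", alpha, graph=build_neighbor_graph(S, 4))
            ] * n_f,
            "nngp_exact": lambda: [
                build_structure(S, "nngp", alpha,
                                graph=build_neighbor_graph(S, n - 1))
            ] * n_f,
        }[backend]()
        M = (state.lam / state.sigma2) @ state.lam.T
        P = sla.block_diag(*[np.linalg.inv(s.covariance()) for s in structs]) \
            + np.kron(M, np.eye(n))
        b = (state.Z - data.X @ state.beta) @ (state.lam / state.sigma2).T
        mean_oracle = np.linalg.solve(P, b.reshape(-1, order="F"))
        cov_oracle = np.linalg.inv(P)
        solver = make_eta_solver(structs, M)
        mean = solver.solve(b).reshape(-1, order="F")
        np.testing.assert_allclose(mean, mean_oracle, atol=1e-6)
        basis = np.eye(n * n_f)
        cov = np.column_stack([
            solver.solve(basis[:, k].reshape(n, n_f, order="F")).reshape(-1, order="F")
            for k in range(n * n_f)
        ])
        np.testing.assert_allclose(cov, cov_oracle, atol=1e-6)
        # the sampled update with zero noise lands on the conditional mean
        update_eta(state, data, structs, ZeroNormalRng())
        np.testing.assert_allclose(
            state.eta.reshape(-1, order="F"), mean_oracle, atol=1e-6
        )

    def test_zero_loadings_give_prior_draws(self, rng):
        n = 5
        S = rng.uniform(size=(n, 2))
        data = CommunityData(
            Y=rng.standard_normal((n, 2)), X=np.ones((n, 1)), S=S
        )
        state = random_state(data, 1, rng)
        state.lam[:] = 0.0
        struct = build_structure(S, "gp", 0.5)
        draws = []
        for _ in range(15_000):
            update_eta(state, data, [struct], rng)
            draws.append(state.eta[:, 0].copy())
        draws = np.array(draws)
        # 4 MC standard errors: 15 distinct covariance entries are
        # compared jointly, so a per-entry 3-SE band would false-alarm
        # on ~5% of runs
        se = 4.0 * np.sqrt(2.0 / len(draws))
        np.testing.assert_allclose(np.cov(draws.T), struct.covariance(), atol=se)

    def test_likelihood_washout_reverts_to_prior_mean_zero(self, rng, small_community):
        state = random_state(small_community, 2, rng)
        state.sigma2[:] = 1e12
        structs = [IdentityStructure(small_community.n_sites)] * 2
        update_eta(state, small_community, structs, ZeroNormalRng())
        np.testing.assert_allclose(state.eta, 0.0, atol=1e-6)


class TestUpdateAlpha:
    def test_degenerate_grid_always_selected(self, rng, small_community):
        state = random_state(small_community, 2, rng)
        cands = CandidateStructures(
            structures=[IdentityStructure(small_community.n_sites)],
            weights=np.array([1.0]),
        )
        update_alpha(state, cands, rng)
        assert (state.alpha_index == 0).all()

    def test_symmetric_candidates_chosen_evenly(self, rng, small_community):
        state = random_state(small_community, 1, rng)
        n = small_community.n_sites
        cands = CandidateStructures(
            structures=[IdentityStructure(n), IdentityStructure(n)],
            weights=np.array([0.5, 0.5]),
        )
        picks = []
        for _ in range(10_000):
            update_alpha(state, cands, rng)
            picks.append(state.alpha_index[0])
        freq = np.mean(picks)
        assert freq == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(10_000))

    def test_transect_consistency_recovers_range(self):
        # eta drawn from a GP with known range on a 1-D transect: the
        # grid posterior mode should sit at or next to the truth
        alpha_true = 0.2
        grid = np.geomspace(0.02, 1.0, 10)
        idx_true = int(np.argmin(np.abs(np.log(grid) - np.log(alpha_true))))
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            x = np.sort(r.uniform(0, 1, 200))
            S = np.column_stack([x, np.zeros(200)])
            K = exp_cov_matrix(S, alpha=alpha_true)
            K[np.diag_indices_from(K)] += 1e-8
            w = np.linalg.cholesky(K) @ r.standard_normal(200)
            lm = [build_structure(S, "gp", a).log_marginal(w) for a in grid]
            hits += abs(int(np.argmax(lm)) - idx_true) <= 1
        assert hits >= 90


class TestUpdateSigma2:
    def make(self, rng, n=20, n_s=2):
        data = CommunityData(
            Y=rng.standard_normal((n, n_s)),
            X=np.ones((n, 1)),
            S=rng.uniform(size=(n, 2)),
        )
        return data, random_state(data, 1, rng)

    def test_inverse_gamma_moments(self, rng):
        data, state = self.make(rng)
        state.Z = data.Y.copy()
        priors = PriorSpec(sigma2_shape=2.0, sigma2_rate=1.0)
        L = data.X @ state.beta + state.eta @ state.lam
        ss = np.sum((state.Z - L) ** 2, axis=0)
        shape = priors.sigma2_shape + 0.5 * data.n_sites
        rate = priors.sigma2_rate + 0.5 * ss
        draws = []
        for _ in range(100_000):
            update_sigma2(state, data, priors, np.array([True, True]), rng)
            draws.append(state.sigma2.copy())
        draws = np.array(draws)
        expected = rate / (shape - 1.0)
        se = (rate / ((shape - 1) * np.sqrt(shape - 2))) / np.sqrt(len(draws))
        np.testing.assert_allclose(draws.mean(axis=0), expected, atol=(3 * se).max())

    def test_zero_residuals_concentrate_near_zero(self, rng):
        data, state = self.make(rng)
        state.Z = data.X @ state.beta + state.eta @ state.lam  # exact fit
        priors = PriorSpec(sigma2_shape=0.001, sigma2_rate=0.001)
        draws = []
        for _ in range(2_000):
            update_sigma2(state, data, priors, np.array([True, True]), rng)
            draws.append(state.sigma2.copy())
        q95 = np.quantile(np.array(draws), 0.95)
        assert q95 < 10 * priors.sigma2_rate / (priors.sigma2_shape + data.n_sites / 2)

    def test_probit_species_keep_unit_variance(self, rng):
        data, state = self.make(rng)
        update_sigma2(state, data, PriorSpec(), np.array([True, False]), rng)
        assert state.sigma2[1] == 1.0


class TestRunGibbs:
    def make_inputs(self, rng, n=6, n_s=2):
        data = CommunityData(
            Y=(rng.uniform(size=(n, n_s)) < 0.5).astype(float),
            X=np.ones((n, 1)),
            S=rng.uniform(size=(n, 2)),
        )
        spec = ModelSpec(n_f=1, spatial_method="none")
        return data, spec

    def test_retention_counts(self, rng):
        data, spec = self.make_inputs(rng)
        out = run_gibbs(data, spec, config=ChainConfig(n_iter=37, n_burn=10,
                                                       thin=4, seed=3))
        assert out.n_draws == (37 - 10) // 4

    def test_empty_retention_is_valid(self, rng):
        data, spec = self.make_inputs(rng)
        out = run_gibbs(data, spec, config=ChainConfig(n_iter=15, n_burn=15,
                                                       thin=2, seed=3))
        assert out.n_draws == 0

    def test_seed_determinism(self, rng):
        data, spec = self.make_inputs(rng)
        cfg = ChainConfig(n_iter=40, n_burn=10, thin=2, seed=11)
        a = run_gibbs(data, spec, config=cfg)
        b = run_gibbs(data, spec, config=cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.Z, b.Z)
        c = run_gibbs(data, spec, config=ChainConfig(n_iter=40, n_burn=10,
                                                     thin=2, seed=12))
        assert not np.array_equal(a.beta[0], c.beta[0])

    def test_support_constraints_every_sweep(self, rng):
        data, spec = self.make_inputs(rng, n=8, n_s=3)
        out = run_gibbs(data, spec, config=ChainConfig(n_iter=30, n_burn=0,
                                                       thin=1, seed=5))
        assert (out.phi > 0).all() and (out.delta > 0).all()
        assert (out.sigma2 == 1.0).all()  # all-probit model
        for d in range(out.n_draws):
            assert np.all((out.Z[d] > 0) == (data.Y > 0.5))

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=10, n_burn=20)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)


class TestSuccessiveConditionalSimulation:
    def test_gibbs_preserves_the_prior_joint(self, rng):
        """Geweke-style check: resampling the data from the current state
        between sweeps must leave the prior marginals invariant."""
        n, n_s, n_f = 10, 3, 1
        S = rng.uniform(size=(n, 2))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        data = CommunityData(Y=np.zeros((n, n_s)), X=X, S=S)
        priors = PriorSpec()
        state = random_state(data, n_f, rng)
        state.lam[:] = 0.1 * rng.standard_normal(state.lam.shape)
        cands = CandidateStructures(
            structures=[IdentityStructure(n)], weights=np.array([1.0])
        )
        gauss = np.array([True] * n_s)
        betas, lams, etas, sig2 = [], [], [], []
        n_sweeps = 6000
        for _ in range(n_sweeps):
            # observation step: regenerate Gaussian data from the state
            L = X @ state.beta + state.eta @ state.lam
            Y = L + np.sqrt(state.sigma2) * rng.standard_normal((n, n_s))
            data.Y = Y
            state.Z = Y.copy()
            update_beta_gamma(state, data, priors, rng)
            update_lambda(state, data, rng)
            update_shrinkage(state, priors, rng)
            update_eta(state, data, [cands[0]], rng)
            update_sigma2(state, data, priors, gauss, rng)
            betas.append(state.beta.copy())
            lams.append(state.lam.copy())
            etas.append(state.eta.copy())
            sig2.append(state.sigma2.copy())
        betas = np.array(betas)[500:]
        lams = np.array(lams)[500:]
        etas = np.array(etas)[500:]
        sig2 = np.array(sig2)[500:]
        # prior marginals: beta ~ N(Gamma, V0) with Gamma ~ N(0,1) -> var 2
        assert abs(betas.mean()) < 0.15
        assert betas.var() == pytest.approx(2.0, rel=0.2)
        # lambda marginal variance: E[1/phi] E[1/tau] = 3 * 1/4 = 0.75
        assert lams.var() == pytest.approx(0.75, rel=0.35)
        # eta ~ N(0, 1) under the nonspatial structure
        assert abs(etas.mean()) < 0.1
        assert etas.var() == pytest.approx(1.0, rel=0.1)
        # sigma2 ~ InvGamma(1, 1): median 1/ln 2
        assert np.median(sig2) == pytest.approx(1.0 / np.log(2.0), rel=0.25)
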