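"""Laplace approximation, hyperparameter grid, mixtures and prediction."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm, poisson

from kroncox import inference, kernels, models, simulate


def single_cell_problem(y, prior_mean=0.0, prior_var=1.0):
    """y ~ Poisson(exp(F)), F ~ N(prior_mean, prior_var) via the offset."""
    return inference.LatentProblem(
        spec=None,
        y=np.array([float(y)]),
        Z=np.array([[1.0]]),
        include=np.array([True]),
        offset=np.array([prior_mean]),
        n_latent=1,
        fe_variance=1.0,
    ), np.array([[np.sqrt(prior_var)]])


def quadrature_posterior(y, prior_mean, prior_var):
    """Exact single-cell posterior mean/sd of eta by dense quadrature."""
    fs = np.linspace(-20, 20, 400001)
    lp = y * (fs + prior_mean) - np.exp(fs + prior_mean) - 0.5 * fs**2 / prior_var
    w = np.exp(lp - lp.max())
    z = np.trapezoid(w, fs)
    mean = np.trapezoid(fs * w, fs) / z
    sd = np.sqrt(np.trapezoid((fs - mean) ** 2 * w, fs) / z)
    return mean, sd


class TestGaussianApprox:
    def test_gaussian_likelihood_one_step_exact(self, rng):
        n, m = 8, 5
        Z = rng.standard_normal((n, m))
        A = rng.standard_normal((m, m))
        Sigma = A @ A.T + np.eye(m)
        y = rng.standard_normal(n)
        s2 = 0.5
        prob = inference.LatentProblem(
            spec=None, y=y, Z=Z, include=np.ones(n, bool), offset=np.zeros(n),
            n_latent=m, fe_variance=1.0, likelihood="gaussian", noise_var=s2,
        )
        ap = inference.gaussian_approx(prob, np.linalg.cholesky(Sigma))
        Q = np.linalg.inv(Sigma) + Z.T @ Z / s2
        mu = np.linalg.solve(Q, Z.T @ y / s2)
        np.testing.assert_allclose(ap.mode, mu, atol=1e-10)
        np.testing.assert_allclose(ap.covariance(), np.linalg.inv(Q), atol=1e-10)
        assert ap.iterations <= 2

    def test_single_cell_mode_matches_exact_maximizer(self):
        prob, L = single_cell_problem(3)
        ap = inference.gaussian_approx(prob, L)
        # mode solves y - exp(f) - f = 0
        from scipy.optimize import brentq

        f_star = brentq(lambda f: 3 - np.exp(f) - f, -10, 10)
        assert ap.mode[0] == pytest.approx(f_star, abs=1e-8)

    def test_single_cell_sd_near_quadrature(self):
        for y in (0, 3, 20):
            prob, L = single_cell_problem(y)
            ap = inference.gaussian_approx(prob, L)
            _, sd = quadrature_posterior(y, 0.0, 1.0)
            assert ap.marginal_sd()[0] == pytest.approx(sd, rel=5e-2)

    def test_all_zero_counts_diffuse_free_mode_at_prior_mean(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        spec = models.specify_model("M1", panel, chain_operator)
        prob = inference.LatentProblem.build(
            spec, panel, counts=np.zeros_like(panel.counts)
        )
        # kill the fixed effects so only the latent field remains
        prob = inference.LatentProblem(
            spec=spec, y=prob.y, Z=prob.Z[:, : prob.n_latent],
            include=prob.include, offset=prob.offset, n_latent=prob.n_latent,
            fe_variance=spec.fixed_effect_variance,
        )
        L = spec.latent_prior_cholesky(panel)
        ap = inference.gaussian_approx(prob, L)
        # with y = 0 everywhere the likelihood pulls exp(F) toward 0 but the
        # prior keeps the mode near 0; all mode entries must be <= 0
        assert ap.mode.max() <= 1e-6

    def test_monotone_objective(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        spec = models.specify_model("M1", panel, chain_operator)
        prob = inference.LatentProblem.build(spec, panel)
        L = prob.prior_cholesky(panel, None)
        ap = inference.gaussian_approx(prob, L, init=prob.default_init())
        assert ap.converged

    def test_nonconvergence_error_carries_trace(self):
        prob, L = single_cell_problem(3)
        with pytest.raises(inference.NonConvergenceError) as ei:
            inference.gaussian_approx(prob, L, max_iter=1)
        assert len(ei.value.trace) >= 1


class TestEvidence:
    def test_matches_closed_form_gaussian_marginal(self, rng):
        n, m = 6, 4
        Z = rng.standard_normal((n, m))
        A = rng.standard_normal((m, m))
        Sigma = A @ A.T + np.eye(m)
        y = rng.standard_normal(n)
        s2 = 0.7
        prob = inference.LatentProblem(
            spec=None, y=y, Z=Z, include=np.ones(n, bool), offset=np.zeros(n),
            n_latent=m, fe_variance=1.0, likelihood="gaussian", noise_var=s2,
        )
        ap = inference.gaussian_approx(prob, np.linalg.cholesky(Sigma))
        ev = inference.log_joint_at_mode(ap, prob)
        truth = multivariate_normal.logpdf(y, np.zeros(n), Z @ Sigma @ Z.T + s2 * np.eye(n))
        assert ev == pytest.approx(truth, abs=1e-8)

    def test_hyper_prior_shift_is_additive(self):
        prob, L = single_cell_problem(3)
        ap = inference.gaussian_approx(prob, L)
        base = inference.log_joint_at_mode(ap, prob, log_hyper_prior=0.0)
        shifted = inference.log_joint_at_mode(ap, prob, log_hyper_prior=1.234)
        assert shifted - base == pytest.approx(1.234)

    def test_prior_variance_ordering_matches_quadrature(self):
        # flat data: doubling the prior variance lowers the evidence in the
        # same direction as exact quadrature says it should
        y = 3

        def exact_evidence(v0):
            fs = np.linspace(-20, 20, 200001)
            lp = (
                y * fs - np.exp(fs)
                - 0.5 * fs**2 / v0
                - 0.5 * np.log(2 * np.pi * v0)
                - np.log(float(__import__("math").factorial(y)))
            )
            return np.log(np.trapezoid(np.exp(lp), fs))

        evs, exacts = [], []
        for v0 in (0.5, 1.0, 2.0):
            prob, L = single_cell_problem(y, prior_var=v0)
            ap = inference.gaussian_approx(prob, L)
            evs.append(inference.log_joint_at_mode(ap, prob))
            exacts.append(exact_evidence(v0))
        assert np.argsort(evs).tolist() == np.argsort(exacts).tolist()


class TestLhsGrid:
    def test_single_point_within_bounds(self):
        g = inference.lhs_grid({"a": (0.1, 10.0)}, 1, seed=0)
        assert g.K == 1
        assert 0.1 <= g.points[0, 0] <= 10.0

    def test_stratification(self):
        g = inference.lhs_grid({"a": (0.1, 10.0), "b": (1.0, 100.0), "c": (0.5, 5.0)}, 10, seed=3)
        for a, name in enumerate(g.names):
            lo, hi = g.bounds[name]
            u = (np.log(g.points[:, a]) - np.log(lo)) / (np.log(hi) - np.log(lo))
            strata = np.floor(u * 10).astype(int)
            assert sorted(strata.tolist()) == list(range(10))

    def test_seed_determinism(self):
        b = {"a": (0.1, 10.0), "b": (1.0, 100.0)}
        g1 = inference.lhs_grid(b, 8, seed=5)
        g2 = inference.lhs_grid(b, 8, seed=5)
        g3 = inference.lhs_grid(b, 8, seed=6)
        np.testing.assert_array_equal(g1.points, g2.points)
        assert not np.array_equal(g1.points, g3.points)

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            inference.lhs_grid({"a": (0.1, 1.0)}, 0, seed=0)


class TestFit:
    def test_single_point_grid_equals_that_approx(self, small_panel, chain_operator):
        panel, _, scen = small_panel
        spec = models.specify_model("M1", panel, chain_operator, kernel_params=scen.kernel_truth)
        grid = inference.HyperGrid(
            names=["sigma2"], points=np.array([[0.3]]), bounds={"sigma2": (0.1, 1.0)}, seed=0
        )
        fm = inference.fit(spec, panel, grid)
        assert fm.weights.tolist() == [1.0]
        mean, sd = fm.marginal_moments()
        np.testing.assert_allclose(mean, fm.approxes[0].mode, atol=1e-12)

    def test_equal_evidence_gives_equal_weights(self, small_panel, chain_operator):
        panel, _, scen = small_panel
        spec = models.specify_model("M1", panel, chain_operator)
        grid = inference.HyperGrid(
            names=["sigma2"], points=np.array([[0.3], [0.3]]),
            bounds={"sigma2": (0.1, 1.0)}, seed=0,
        )
        fm = inference.fit(spec, panel, grid)
        np.testing.assert_allclose(fm.weights, [0.5, 0.5], atol=1e-12)

    def test_weights_sum_to_one_and_reproducible(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        spec = models.specify_model("M1", panel, chain_operator)
        grid = inference.lhs_grid(
            {"sigma2": (0.05, 2.0), "rho_p": (0.2, 20.0), "rho_rbf": (5.0, 500.0)}, 5, seed=2
        )
        fm1 = inference.fit(spec, panel, grid)
        fm2 = inference.fit(spec, panel, grid)
        assert fm1.weights.sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(fm1.weights, fm2.weights)
        np.testing.assert_array_equal(
            fm1.marginal_summary().values, fm2.marginal_summary().values
        )

    def test_dominated_point_negligible(self, small_panel, chain_operator):
        panel, _, scen = small_panel
        spec = models.specify_model("M1", panel, chain_operator)
        # one sensible point and one absurd point: the absurd one's weight
        # vanishes and dropping it barely moves the summaries
        grid2 = inference.HyperGrid(
            names=["sigma2", "rho_p", "rho_rbf"],
            points=np.array([[0.3, 1.0, 50.0], [1e3, 1e3, 1e6]]),
            bounds={"sigma2": (0.1, 1e4), "rho_p": (0.1, 1e4), "rho_rbf": (1.0, 1e7)},
            seed=0,
        )
        fm2 = inference.fit(spec, panel, grid2)
        if len(fm2.approxes) == 2:
            k = int(np.argmin(fm2.weights))
            assert fm2.weights[k] < 1e-6
        mean2, _ = fm2.marginal_moments()
        grid1 = inference.HyperGrid(
            names=["sigma2", "rho_p", "rho_rbf"],
            points=np.array([[0.3, 1.0, 50.0]]),
            bounds=grid2.bounds,
            seed=0,
        )
        fm1 = inference.fit(spec, panel, grid1)
        mean1, _ = fm1.marginal_moments()
        assert np.abs(mean1 - mean2).max() < 1e-5

    def test_marginal_quantiles_ordered(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        spec = models.specify_model("M1", panel, chain_operator)
        grid = inference.lhs_grid(
            {"sigma2": (0.05, 2.0), "rho_p": (0.2, 20.0), "rho_rbf": (5.0, 500.0)}, 4, seed=1
        )
        fm = inference.fit(spec, panel, grid)
        s = fm.marginal_summary()
        assert (s["q2.5"] <= s["q50"]).all() and (s["q50"] <= s["q97.5"]).all()


class TestInformationCriteria:
    def test_waic_point_mass_posterior(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        # shrink all prior variances to (almost) zero: posterior ~ point mass
        spec = models.specify_model(
            "M1", panel, chain_operator,
            kernel_params=kernels.KernelParams(sigma2=1e-12),
            fixed_effect_variance=1e-12,
        )
        grid = inference.HyperGrid(["sigma2"], np.array([[1e-12]]), {"sigma2": (1e-13, 1e-11)}, 0)
        fm = inference.fit(spec, panel, grid)
        w = inference.waic(fm, n_draws=400, seed=0)
        lam = np.ones(panel.counts.size)  # eta == 0 everywhere
        expected = -2 * poisson.logpmf(panel.counts.T.reshape(-1), 1.0).sum()
        assert w == pytest.approx(expected, rel=1e-3)

    def test_waic_matches_analytic_gaussian_toy(self, rng):
        # conjugate scalar toy: y_i | mu ~ N(mu, s2), mu ~ N(0, v0)
        n, s2, v0 = 12, 0.8, 2.0
        y = rng.normal(1.0, np.sqrt(s2), n)
        prob = inference.LatentProblem(
            spec=None, y=y, Z=np.ones((n, 1)), include=np.ones(n, bool),
            offset=np.zeros(n), n_latent=1, fe_variance=1.0,
            likelihood="gaussian", noise_var=s2,
        )
        ap = inference.gaussian_approx(prob, np.array([[np.sqrt(v0)]]))
        qv = 1.0 / (1.0 / v0 + n / s2)
        qm = qv * y.sum() / s2
        assert ap.mode[0] == pytest.approx(qm, abs=1e-10)
        # WAIC terms have closed forms for Gaussian posterior + likelihood
        draws = qm + np.sqrt(qv) * np.random.default_rng(0).standard_normal(200000)
        lp = norm.logpdf(y[:, None], draws[None, :], np.sqrt(s2))
        lppd = np.log(np.exp(lp - lp.max(1, keepdims=True)).mean(1)) + lp.max(1)
        p = lp.var(1, ddof=1)
        waic_mc = -2 * (lppd - p).sum()
        # analytic: E[logp] and Var[logp] available since logp is quadratic in mu
        lppd_exact = norm.logpdf(y, qm, np.sqrt(s2 + qv))
        var_exact = (qv / s2) * ((y - qm) ** 2) + qv**2 / (2 * s2**2)
        waic_exact = -2 * (lppd_exact - var_exact).sum()
        assert waic_mc == pytest.approx(waic_exact, rel=0.02)

    def test_duplicating_cells_doubles_deviance_terms(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        spec = models.specify_model(
            "M1", panel, chain_operator,
            kernel_params=kernels.KernelParams(sigma2=1e-12),
            fixed_effect_variance=1e-12,
        )
        grid = inference.HyperGrid(["sigma2"], np.array([[1e-12]]), {"sigma2": (1e-13, 1e-11)}, 0)
        fm = inference.fit(spec, panel, grid)
        d1 = inference.dic(fm, n_draws=400, seed=0)
        # doubling data by exact duplication doubles the deviance
        import pandas as pd

        from kroncox.surrogates import ClusterPanel

        panel2 = ClusterPanel(
            counts=np.vstack([panel.counts, panel.counts]),
            covariates=np.vstack([panel.covariates, panel.covariates]),
            cluster_populations=np.concatenate(
                [panel.cluster_populations, panel.cluster_populations]
            ),
            time_index=panel.time_index,
        )
        theta = np.eye(8)
        spec2 = models.specify_model(
            "M1R", panel2, kernel_params=kernels.KernelParams(sigma2=1e-12), tau=1e12,
            fixed_effect_variance=1e-12,
        )
        grid2 = inference.HyperGrid(["tau"], np.array([[1e12]]), {"tau": (1e11, 1e13)}, 0)
        fm2 = inference.fit(spec2, panel2, grid2)
        d2 = inference.dic(fm2, n_draws=400, seed=0)
        assert d2 == pytest.approx(2 * d1, rel=1e-3)


class TestPosteriorPredictive:
    def test_pinned_zero_latent_is_poisson_one(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        spec = models.specify_model(
            "M1", panel, chain_operator,
            kernel_params=kernels.KernelParams(sigma2=1e-12),
            fixed_effect_variance=1e-12,
        )
        grid = inference.HyperGrid(["sigma2"], np.array([[1e-12]]), {"sigma2": (1e-13, 1e-11)}, 0)
        cells = [(0, panel.n_periods - 1)]
        pred = inference.posterior_predictive(spec, panel, grid, cells, n_draws=20000, seed=1)
        assert pred.mean[0] == pytest.approx(1.0, abs=0.05)
        assert pred.lower[0] == 0.0
        assert pred.upper[0] == 3.0  # exact 97.5% quantile of Poisson(1)

    def test_rolling_h1_equals_simultaneous(self, small_panel, chain_operator):
        panel, _, scen = small_panel
        spec = models.specify_model("M1", panel, chain_operator, kernel_params=scen.kernel_truth)
        grid = inference.HyperGrid(
            ["sigma2"], np.array([[0.3]]), {"sigma2": (0.1, 1.0)}, 0
        )
        cells = [(c, panel.n_periods - 1) for c in range(panel.n_clusters)]
        ps = inference.posterior_predictive(spec, panel, grid, cells, "simultaneous", 500, seed=9)
        pr = inference.posterior_predictive(spec, panel, grid, cells, "rolling", 500, seed=9)
        np.testing.assert_allclose(ps.mean, pr.mean, rtol=1e-10)

    def test_out_of_panel_cell_rejected(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        spec = models.specify_model("M1", panel, chain_operator)
        grid = inference.HyperGrid(["sigma2"], np.array([[0.3]]), {"sigma2": (0.1, 1.0)}, 0)
        with pytest.raises(ValueError, match="outside the panel"):
            inference.posterior_predictive(spec, panel, grid, [(0, 99)])

    def test_missing_covariates_named(self, small_panel, chain_operator):
        panel, _, _ = small_panel
        panel.covariates[1, 3, 0] = np.nan
        spec = models.specify_model("M1", panel, chain_operator)
        grid = inference.HyperGrid(["sigma2"], np.array([[0.3]]), {"sigma2": (0.1, 1.0)}, 0)
        with pytest.raises(ValueError, match="missing covariates"):
            inference.posterior_predictive(spec, panel, grid, [(0, 35)])
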