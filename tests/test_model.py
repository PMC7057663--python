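"""Joint covariance, likelihood, MLE fitting and derived summaries."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from shapely.geometry import box

from arealgp.geometry import AreaUnit, FactorTable, build_quadrature_grid
from arealgp.model import (
    FULL,
    NO_COVARIATE,
    FittedModel,
    MisalignedData,
    ModelError,
    ModelParams,
    _mean_vector,
    build_joint_covariance,
    cross_group_correlation,
    exp_cov,
    fit_mle,
    fit_report_table,
    log_likelihood,
    lr_test,
    practical_range,
    variance_explained,
)
from arealgp.simulate import gp_cholesky, make_scenario, simulate_dataset


def random_params(rng, with_beta=True):
    w1, w2 = rng.uniform(0.5, 4.0, 2)
    rho = rng.uniform(-0.8, 0.8)
    w12 = rho * np.sqrt(w1 * w2)
    return ModelParams(
        alpha=rng.normal(75, 3, 2),
        beta=rng.normal(0, 0.3, 2) if with_beta else np.zeros(2),
        gamma=rng.normal(30, 5),
        tau2=rng.uniform(5, 60),
        delta=rng.uniform(300, 3000),
        nu2=rng.uniform(0.5, 5),
        omega=np.array([[w1, w12], [w12, w2]]),
    )


class TestModelParams:
    def test_vector_round_trip(self):
        p = random_params(np.random.default_rng(0))
        q = ModelParams.from_vector(p.to_vector(), FULL)
        np.testing.assert_allclose(q.omega, p.omega, rtol=1e-10)
        assert q.delta == pytest.approx(p.delta)

    def test_invalid_omega_rejected(self):
        with pytest.raises(ModelError, match="positive definite"):
            ModelParams(
                alpha=np.zeros(2), beta=np.zeros(2), gamma=0.0,
                tau2=1.0, delta=1.0, nu2=1.0,
                omega=np.array([[1.0, 1.5], [1.5, 1.0]]),
            )

    def test_negative_variance_rejected(self):
        with pytest.raises(ModelError):
            ModelParams(
                alpha=np.zeros(2), beta=np.zeros(2), gamma=0.0,
                tau2=-1.0, delta=1.0, nu2=1.0, omega=np.eye(2),
            )


class TestExpCov:
    def test_zero_distance(self):
        assert exp_cov(0.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_closed_form(self):
        assert exp_cov(2000.0, 1.0, 2000.0) == pytest.approx(np.exp(-1.0))

    def test_scale_invariance(self):
        assert exp_cov(700.0, 2.0, 900.0) == pytest.approx(exp_cov(1400.0, 2.0, 1800.0))

    def test_strictly_decreasing(self):
        d = np.linspace(0, 5000, 50)
        v = exp_cov(d, 3.0, 800.0)
        assert np.all(np.diff(v) < 0)

    def test_negative_distance_errors(self):
        with pytest.raises(ModelError):
            exp_cov(-1.0, 1.0, 1.0)


@pytest.fixture(scope="module")
def tiny_instance():
    """3 coarse / 6 fine Voronoi cells with a simulated dataset."""
    scen = make_scenario(
        domain_size=4000.0, n_coarse=3, n_fine=6, seed=21, sim_grid_spacing=250.0
    )
    sim = simulate_dataset(scen, seed=22)
    grid = sim.sim_grid
    ft = FactorTable(scen.coarse_units, scen.fine_units, grid)
    return scen, sim, grid, ft


class TestJointCovariance:
    def test_beta_zero_decouples(self, tiny_instance):
        scen, sim, grid, ft = tiny_instance
        rng = np.random.default_rng(1)
        p = random_params(rng, with_beta=False)
        S = build_joint_covariance(p, sim.data, grid, factors=ft, jitter=False)
        n, m = sim.data.n, sim.data.m
        assert np.allclose(S[: 2 * n, 2 * n :], 0.0)
        np.testing.assert_allclose(
            S[:n, :n], p.omega[0, 0] * np.eye(n), atol=1e-12
        )
        np.testing.assert_allclose(
            S[:n, n : 2 * n], p.omega[0, 1] * np.eye(n), atol=1e-12
        )

    def test_simulation_oracle(self, tiny_instance):
        """Joint covariance blocks match 20,000 simulated datasets."""
        scen, sim, grid, ft = tiny_instance
        p = scen.true_params
        S_model = build_joint_covariance(p, sim.data, grid, factors=ft, jitter=False)
        n, m = sim.data.n, sim.data.m
        L = gp_cholesky(grid.points, p.tau2, p.delta)
        rng = np.random.default_rng(42)
        B = 20_000
        U = L @ rng.standard_normal((L.shape[0], B))
        lc, lf = grid.labels(scen.coarse_units), grid.labels(scen.fine_units)
        Uc = np.stack([U[lc == j].mean(axis=0) for j in range(n)])
        Uf = np.stack([U[lf == k].mean(axis=0) for k in range(m)])
        T = rng.multivariate_normal(np.zeros(2), p.omega, size=(B, n))
        V = rng.normal(0, np.sqrt(p.nu2), size=(B, m))
        stack = np.hstack(
            [
                p.alpha[0] + p.beta[0] * Uc.T + T[:, :, 0],
                p.alpha[1] + p.beta[1] * Uc.T + T[:, :, 1],
                p.gamma + Uf.T + V,
            ]
        )
        emp = np.cov(stack.T)
        var = np.diag(emp)
        se = np.sqrt((np.outer(var, var) + emp**2) / B)
        assert np.all(np.abs(emp - S_model) <= 3 * se)


class TestLogLikelihood:
    def test_three_by_three_closed_form(self):
        """n=1, m=1 with near-point units equals the trivariate normal density."""
        cu = AreaUnit(id="c", partition="coarse", polygon=box(124, 124, 126, 126))
        fu = AreaUnit(id="f", partition="fine", polygon=box(624, 124, 626, 126))
        grid = build_quadrature_grid([cu, fu], 2.0)  # one point per tiny unit
        p = ModelParams(
            alpha=np.array([70.0, 80.0]), beta=np.array([-0.2, 0.1]), gamma=25.0,
            tau2=4.0, delta=800.0, nu2=1.5,
            omega=np.array([[2.0, 0.5], [0.5, 1.0]]),
        )
        data = MisalignedData(
            coarse_units=[cu], fine_units=[fu],
            outcome=np.array([[69.0, 80.5]]), covariate=np.array([27.0]),
        )
        # hand-built 3x3 covariance: units are single points 500 m apart
        r = np.exp(-500.0 / p.delta)
        b1, b2 = p.beta
        S = np.array(
            [
                [b1 * b1 * p.tau2 + 2.0, b1 * b2 * p.tau2 + 0.5, b1 * p.tau2 * r],
                [b1 * b2 * p.tau2 + 0.5, b2 * b2 * p.tau2 + 1.0, b2 * p.tau2 * r],
                [b1 * p.tau2 * r, b2 * p.tau2 * r, p.tau2 + 1.5],
            ]
        )
        expected = multivariate_normal.logpdf(
            [69.0, 80.5, 27.0], [70.0, 80.0, 25.0], S
        )
        got = log_likelihood(p, data, grid)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_factorised_equals_stacked(self, tiny_instance):
        scen, sim, grid, ft = tiny_instance
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = random_params(rng)
            ll = log_likelihood(p, sim.data, grid, ft)
            S = build_joint_covariance(p, sim.data, grid, factors=ft)
            mu = _mean_vector(p, sim.data.n, sim.data.m)
            ll2 = multivariate_normal.logpdf(sim.data.stacked(), mu, S)
            assert ll == pytest.approx(ll2, rel=1e-6)

    def test_beta_zero_separates(self, tiny_instance):
        scen, sim, grid, ft = tiny_instance
        p = random_params(np.random.default_rng(4), with_beta=False)
        n, m = sim.data.n, sim.data.m
        ll = log_likelihood(p, sim.data, grid, ft)
        S = build_joint_covariance(p, sim.data, grid, factors=ft)
        y = np.concatenate([sim.data.outcome[:, 0], sim.data.outcome[:, 1]])
        mu = _mean_vector(p, n, m)
        ll_leb = multivariate_normal.logpdf(y, mu[: 2 * n], S[: 2 * n, : 2 * n])
        ll_imd = multivariate_normal.logpdf(
            sim.data.covariate, mu[2 * n :], S[2 * n :, 2 * n :]
        )
        assert ll == pytest.approx(ll_leb + ll_imd, rel=1e-6)


class TestFitMLE:
    def test_parameter_recovery(self, desk_scenario):
        """Median |estimate - truth| / SE stays below 3 across replicates."""
        scen = desk_scenario
        p = scen.true_params
        sim_grid = build_quadrature_grid(
            scen.coarse_units + scen.fine_units, scen.sim_grid_spacing
        )
        chol = gp_cholesky(sim_grid.points, p.tau2, p.delta)
        ft = FactorTable(scen.coarse_units, scen.fine_units, sim_grid)
        truth = p.to_vector(FULL)
        zs = []
        for rep in range(12):
            sim = simulate_dataset(scen, seed=300 + rep, sim_grid=sim_grid, chol=chol)
            fit = fit_mle(
                sim.data, sim_grid,
                options={"n_starts": 1, "seed": 0, "factors": ft},
            )
            se = np.sqrt(np.clip(np.diag(fit.vcov), 1e-12, None))
            zs.append(np.abs(fit.params_hat.to_vector(FULL) - truth) / se)
        med = np.median(np.array(zs), axis=0)
        assert np.all(med < 3.0)

    def test_nested_loglik_and_lr(self, small_setup, small_fit):
        scen, sim, grid, ft = small_setup
        reduced = fit_mle(
            sim.data, grid, variant=NO_COVARIATE,
            options={"n_starts": 2, "seed": 0, "factors": ft},
        )
        assert small_fit.loglik >= reduced.loglik - 1e-6
        res = lr_test(small_fit, reduced)
        assert res.statistic >= 0
        assert 0 <= res.pvalue <= 1

    def test_refit_from_mle_is_fixed_point(self, small_setup, small_fit):
        scen, sim, grid, ft = small_setup
        refit = fit_mle(
            sim.data, grid, init=small_fit.params_hat,
            options={"n_starts": 1, "seed": 0, "factors": ft, "compute_ci": False},
        )
        assert abs(refit.loglik - small_fit.loglik) < 1e-4

    def test_covariate_shift_invariance(self, small_setup, small_fit):
        scen, sim, grid, ft = small_setup
        shifted = MisalignedData(
            coarse_units=sim.data.coarse_units,
            fine_units=sim.data.fine_units,
            outcome=sim.data.outcome,
            covariate=sim.data.covariate + 10.0,
        )
        fit2 = fit_mle(
            shifted, grid, options={"n_starts": 2, "seed": 0, "factors": ft,
                                    "compute_ci": False},
        )
        assert fit2.params_hat.gamma == pytest.approx(
            small_fit.params_hat.gamma + 10.0, abs=1e-2
        )
        np.testing.assert_allclose(
            fit2.params_hat.beta, small_fit.params_hat.beta, atol=1e-3
        )
        assert fit2.loglik == pytest.approx(small_fit.loglik, abs=1e-3)

    def test_degenerate_inputs_rejected(self, small_setup):
        scen, sim, grid, ft = small_setup
        const = MisalignedData(
            coarse_units=sim.data.coarse_units,
            fine_units=sim.data.fine_units,
            outcome=sim.data.outcome,
            covariate=np.full(sim.data.m, 5.0),
        )
        with pytest.raises(ModelError, match="constant covariate"):
            fit_mle(const, grid)

    def test_report_table_has_loglik_row(self, small_fit):
        table = fit_report_table(small_fit)
        assert "log_likelihood" in set(table["parameter"])
        assert {"parameter", "estimate", "ci_low", "ci_high"} <= set(table.columns)


class TestDerivedSummaries:
    def test_variance_explained_zero_beta(self):
        assert variance_explained(0.0, 10.0, 2.0) == 0.0

    def test_variance_explained_symmetric_point(self):
        assert variance_explained(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_variance_explained_increasing_in_beta(self):
        vals = [variance_explained(b, 5.0, 2.0) for b in (0.1, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(vals) > 0)

    def test_cross_group_correlation_identity(self):
        assert cross_group_correlation(np.eye(2)) == 0.0

    def test_cross_group_correlation_boundary(self):
        eps = 1e-6
        om = np.array([[1.0, 1.0 - eps], [1.0 - eps, 1.0]])
        assert cross_group_correlation(om) == pytest.approx(1.0, abs=1e-5)

    def test_practical_range_closed_form(self):
        assert practical_range(1.0, 0.05) == pytest.approx(-np.log(0.05))
        assert practical_range(1.0, 1.0) == 0.0

    def test_lr_identical_logliks(self, small_fit):
        clone = FittedModel(
            params_hat=small_fit.params_hat, loglik=small_fit.loglik,
            vcov=small_fit.vcov, confint=small_fit.confint,
            convergence=small_fit.convergence, model_variant=NO_COVARIATE,
            param_names=small_fit.param_names,
        )
        res = lr_test(small_fit, clone)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_lr_power_with_strong_association(self):
        """A strong covariate effect is detected with p < 0.001."""
        strong = ModelParams(
            alpha=np.array([75.0, 81.0]), beta=np.array([-0.6, -0.5]), gamma=30.0,
            tau2=50.0, delta=1200.0, nu2=2.0,
            omega=np.array([[1.0, 0.3], [0.3, 1.0]]),
        )
        scen = make_scenario(
            domain_size=5000.0, n_coarse=8, n_fine=16, seed=31,
            sim_grid_spacing=250.0, true_params=strong,
        )
        sim = simulate_dataset(scen, seed=32)
        grid = sim.sim_grid
        ft = FactorTable(scen.coarse_units, scen.fine_units, grid)
        opts = {"n_starts": 1, "seed": 0, "factors": ft, "compute_ci": False}
        full = fit_mle(sim.data, grid, options=dict(opts))
        red = fit_mle(sim.data, grid, variant=NO_COVARIATE, options=dict(opts))
        assert lr_test(full, red).pvalue < 1e-3
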