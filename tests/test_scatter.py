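import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glandfrac._mle import closed_form, dloglik, loglik, solve_exp_poisson
from glandfrac.scatter import ml_scatter_removal, scatter_model_for_estimation
from glandfrac.simulate import simulate_projection, spr_value


class TestDerivatives:
    def test_analytic_derivatives_match_finite_differences(self):
        rng = np.random.default_rng(0)
        n = rng.uniform(50, 5000, 20)
        a = rng.uniform(1000, 50000, 20)
        b = rng.uniform(1.0, 9.0, 20)
        s = rng.uniform(0, 500, 20)
        theta = rng.uniform(0.05, 1.2, 20)
        h = 1e-6
        d1, d2 = dloglik(theta, n, a, b, s)
        fd1 = (loglik(theta + h, n, a, b, s) - loglik(theta - h, n, a, b, s)) / (2 * h)
        fd2 = (loglik(theta + h, n, a, b, s) - 2 * loglik(theta, n, a, b, s)
               + loglik(theta - h, n, a, b, s)) / h**2
        np.testing.assert_allclose(d1, fd1, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(d2, fd2, rtol=1e-3, atol=1e-3)


class TestMlScatterRemoval:
    def test_unattenuated_pixel_gives_zero_mu(self):
        im = np.array([[1000.0]])
        res = ml_scatter_removal(im, np.array([[1000.0]]), np.zeros((1, 1)),
                                 np.array([[4.0]]))
        assert res.mu[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert res.iq[0, 0] == pytest.approx(1000.0)

    def test_noiseless_recovery_over_mu_spr_grid(self):
        """On exact expectations the ML solution equals the closed form
        -ln((Im-Sc)/I0)/t over mu in [0.05,1.5]/cm and SPR in [0,1]."""
        mu_star, spr = np.meshgrid(np.linspace(0.05, 1.5, 30), np.linspace(0, 1, 11))
        i0 = 30000.0
        t = 4.5
        primary = i0 * np.exp(-mu_star * t)
        im = primary + spr * primary
        res = ml_scatter_removal(im, np.full_like(im, i0), spr * primary,
                                 np.full_like(im, t))
        assert res.converged.all()
        np.testing.assert_allclose(res.mu, mu_star, atol=1e-10)

    def test_newton_from_crude_start_lands_on_closed_form(self):
        """Oracle equivalence: the iteration, started far from the optimum,
        still finds the analytic one-parameter ML root."""
        rng = np.random.default_rng(5)
        n = 100000
        mu_star = rng.uniform(0.05, 1.5, n)
        spr = rng.uniform(0, 1, n)
        t = rng.uniform(2.0, 9.5, n)
        i0 = 30000.0
        im = rng.poisson(i0 * np.exp(-mu_star * t) * (1 + spr)).astype(float)
        sc = spr / (1 + spr) * im
        ok = im - sc > 1
        res = solve_exp_poisson(im[ok], i0, t[ok], sc[ok], theta0=0.75)
        expected = closed_form(im[ok], i0, t[ok], sc[ok])
        assert res.converged.all()
        np.testing.assert_allclose(res.theta, expected, atol=1e-8)

    def test_brute_force_likelihood_scan_confirms_maximizer(self):
        im, i0, sc, t = 812.0, 30000.0, 240.0, 5.0
        res = ml_scatter_removal(np.array([[im]]), np.array([[i0]]),
                                 np.array([[sc]]), np.array([[t]]))
        grid = np.linspace(0.01, 1.5, 20001)
        ll = loglik(grid, im, i0, t, sc)
        assert abs(res.mu[0, 0] - grid[np.argmax(ll)]) < 2 * (grid[1] - grid[0])

    def test_estimator_nearly_unbiased_on_poisson_batch(self):
        mu_star, t, spr, i0 = 0.5, 4.5, 0.5, 30000.0
        rng = np.random.default_rng(11)
        lam = i0 * np.exp(-mu_star * t) * (1 + spr)
        im = rng.poisson(lam, size=100000).astype(float)
        sc = np.full_like(im, spr * i0 * np.exp(-mu_star * t))
        res = ml_scatter_removal(im[None], np.full_like(im, i0)[None], sc[None],
                                 np.full_like(im, t)[None])
        mu_hat = res.mu[0]
        se = mu_hat.std() / np.sqrt(mu_hat.size)
        assert abs(mu_hat.mean() - mu_star) < 3 * se + 1e-4

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(extra=st.floats(1.0, 300.0))
    def test_more_modeled_scatter_raises_estimated_mu(self, extra):
        """With Im fixed, attributing more of it to scatter leaves less
        primary signal, so the fitted attenuation strictly increases (and
        the corrected counts Iq strictly decrease)."""
        im, i0, t = 900.0, 30000.0, 4.0
        lo = ml_scatter_removal(np.array([[im]]), np.array([[i0]]),
                                np.array([[100.0]]), np.array([[t]])).mu[0, 0]
        hi = ml_scatter_removal(np.array([[im]]), np.array([[i0]]),
                                np.array([[100.0 + extra]]), np.array([[t]])).mu[0, 0]
        assert hi > lo

    def test_scatter_free_correction_is_identity_on_counts(self):
        im = np.array([[500.0, 900.0], [1200.0, 300.0]])
        res = ml_scatter_removal(im, np.full((2, 2), 30000.0), np.zeros((2, 2)),
                                 np.full((2, 2), 4.0))
        np.testing.assert_allclose(res.iq, im, rtol=1e-10)

    def test_non_physical_and_censored_pixels_are_flagged(self):
        im = np.array([[100.0, 0.0, 900.0]])
        sc = np.array([[150.0, 0.0, 100.0]])
        res = ml_scatter_removal(im, np.full((1, 3), 1e4), sc, np.full((1, 3), 4.0))
        assert res.n_non_physical == 1
        assert res.n_censored == 1
        assert res.mask.sum() == 1
        assert np.isnan(res.mu[0, 0]) and np.isnan(res.mu[0, 1])

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ml_scatter_removal(np.ones((1, 1)), np.zeros((1, 1)),
                               np.zeros((1, 1)), np.ones((1, 1)))
        with pytest.raises(ValueError):
            ml_scatter_removal(np.ones((1, 1)), np.ones((1, 1)),
                               -np.ones((1, 1)), np.ones((1, 1)))


class TestScatterModelForEstimation:
    def test_limits(self):
        im = np.full((2, 2), 800.0)
        t0 = np.zeros((2, 2))       # SPR(0) = 0
        assert np.all(scatter_model_for_estimation(None, im, t0) == 0)
        from glandfrac.simulate import SprModel
        unit = SprModel(thicknesses=np.array([0.0, 20.0]), spr=np.array([1.0, 1.0]))
        np.testing.assert_allclose(
            scatter_model_for_estimation(None, im, np.full((2, 2), 4.0), unit),
            im / 2)

    def test_tracks_generator_scatter_within_5pct_rms(self, cell_4cm_20):
        """The estimation-side model reproduces the simulator's stored
        scatter raster over the glandular interior."""
        _, paths, img = cell_4cm_20
        interior = paths.glandular_interior(2)
        sc = scatter_model_for_estimation(img.i0, img.measured, paths.t_breast)
        rel = (sc[interior] - img.scatter[interior]) / img.scatter[interior]
        assert np.sqrt(np.mean(rel**2)) < 0.05
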