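import numpy as np
import pytest

from glandfrac._mle import loglik
from glandfrac.gf import (
    TissueModel,
    compute_vgf,
    estimate_gf_from_sim,
    ml_gf,
    rescale_m,
)
from glandfrac.materials import mu_at
from glandfrac.phantom import build_phantom, trace_paths
from glandfrac.simulate import simulate_projection
from glandfrac.spectrum import EnergySpectrum


def _model(tables, e=21.0, j=0.111, k=0.064):
    return TissueModel.at_energy(e, np.array([[j]]), np.array([[k]]), tables)


def _forward(model, m1, i0, t):
    mu1 = model.mu_known() + (model.mu_g - model.mu_a) * m1
    return i0 * np.exp(-mu1 * t)


class TestMlGf:
    def test_pure_adipose_interior_recovers_zero(self, tables):
        model = _model(tables)
        t = np.array([[4.5]])
        iq = _forward(model, 0.0, 30000.0, t)
        gf = ml_gf(iq, np.array([[3e4]]), t, t - 0.5, model)
        assert gf.m[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_grid_recovery_against_closed_form(self, tables):
        """Any (m1*, j, k) grid point inverts exactly: the one-parameter
        Poisson likelihood's stationary point has an analytic form."""
        for j in (0.05, 0.111, 0.2):
            for k in (0.0, 0.064, 0.15):
                for m1_star in (0.0, 0.1, 0.3, 0.6, 0.8 - j - k):
                    model = _model(tables, j=j, k=k)
                    t = np.array([[5.0]])
                    iq = _forward(model, m1_star, 30000.0, t)
                    gf = ml_gf(iq, np.array([[3e4]]), t, t - 0.5, model)
                    assert gf.m1[0, 0] == pytest.approx(m1_star, abs=1e-10)

    def test_newton_from_crude_start_matches_closed_form(self, tables):
        rng = np.random.default_rng(9)
        n = 100000
        m1_star = rng.uniform(0.0, 0.8, n)
        t = rng.uniform(2.5, 9.5, n)
        model = TissueModel.at_energy(21.0, np.full(n, 0.1), np.full(n, 0.05), tables)
        iq = rng.poisson(_forward(model, m1_star, 30000.0, t)).astype(float)
        gf = ml_gf(iq, np.full(n, 3e4), t, t - 0.5, model, theta0=np.full(n, 0.4))
        closed = ((-np.log(iq / 3e4) / t - model.mu_known())
                  / (model.mu_g - model.mu_a))
        ok = gf.mask
        assert gf.converged[ok].all()
        np.testing.assert_allclose(gf.m1[ok], closed[ok], atol=1e-8)

    def test_brute_force_likelihood_scan_confirms_maximizer(self, tables):
        model = _model(tables)
        t = 5.5
        iq = 1234.0
        gf = ml_gf(np.array([[iq]]), np.array([[3e4]]), np.array([[t]]),
                   np.array([[t - 0.5]]), model)
        grid = np.linspace(-0.2, 1.2, 28001)
        a = 3e4 * np.exp(-model.mu_known()[0, 0] * t)
        b = (model.mu_g - model.mu_a) * t
        ll = loglik(grid, iq, a, b, 0.0)
        assert abs(gf.m1[0, 0] - grid[np.argmax(ll)]) < 2 * (grid[1] - grid[0])

    def test_lower_counts_mean_more_glandular(self, tables):
        model = _model(tables)
        t = np.array([[4.5]])
        hi = ml_gf(np.array([[2000.0]]), np.array([[3e4]]), t, t - 0.5, model)
        lo = ml_gf(np.array([[1500.0]]), np.array([[3e4]]), t, t - 0.5, model)
        assert lo.m1[0, 0] > hi.m1[0, 0]

    def test_sub_adipose_flagged_not_dropped(self, tables):
        model = _model(tables)
        t = np.array([[4.5]])
        iq = _forward(model, -0.05, 30000.0, t)  # brighter than pure adipose
        gf = ml_gf(iq, np.array([[3e4]]), t, t - 0.5, model)
        assert gf.sub_adipose[0, 0]
        assert gf.m1[0, 0] == pytest.approx(-0.05, abs=1e-8)

    def test_nonpositive_iq_excluded(self, tables):
        model = TissueModel.at_energy(21.0, np.full(2, 0.1), np.full(2, 0.05), tables)
        gf = ml_gf(np.array([0.0, 500.0]), np.full(2, 3e4), np.full(2, 4.5),
                   np.full(2, 4.0), model)
        assert not gf.mask[0] and gf.mask[1]

    def test_tissue_model_invariants(self, tables):
        with pytest.raises(ValueError):
            TissueModel(mu_l=0.5, mu_s=0.6, mu_a=0.8, mu_g=0.5,
                        j=np.array([0.1]), k=np.array([0.1]))
        with pytest.raises(ValueError):
            TissueModel(mu_l=0.5, mu_s=0.6, mu_a=0.5, mu_g=0.8,
                        j=np.array([0.6]), k=np.array([0.5]))


class TestRescale:
    def test_arithmetic(self):
        assert rescale_m(0.2, 4.5, 4.0) == pytest.approx(0.225)

    def test_no_paddles_is_identity(self):
        m1 = np.array([0.1, 0.4])
        np.testing.assert_allclose(rescale_m(m1, np.full(2, 4.0), np.full(2, 4.0)), m1)

    def test_end_to_end_algebraic_identity(self, tables):
        """m from the closed-form m1 equals t_g/t_breast for a synthetic
        pixel built from known intercepts."""
        t_lex, t_sk, t_ad, t_g = 0.5, 0.29, 2.71, 1.0
        t = t_lex + t_sk + t_ad + t_g
        e = 21.0
        mu = {n: mu_at(tables[n], e) for n in ("lexan", "skin", "adipose", "glandular")}
        iq = 3e4 * np.exp(-(mu["lexan"] * t_lex + mu["skin"] * t_sk
                            + mu["adipose"] * t_ad + mu["glandular"] * t_g))
        model = TissueModel.at_energy(e, np.array([[t_lex / t]]), np.array([[t_sk / t]]),
                                      tables)
        gf = ml_gf(np.array([[iq]]), np.array([[3e4]]), np.array([[t]]),
                   np.array([[t - t_lex]]), model)
        assert gf.m[0, 0] == pytest.approx(t_g / (t - t_lex), abs=1e-10)

    def test_zero_breast_masked(self):
        out = rescale_m(np.array([0.2]), np.array([4.5]), np.array([0.0]))
        assert np.isnan(out[0])


class TestVgf:
    def test_uniform_field(self, tables):
        model = _model(tables)
        t = np.full((3, 3), 4.5)
        iq = _forward(model, 0.3 * 4.0 / 4.5, 3e4, t)
        gf = ml_gf(iq, np.full((3, 3), 3e4), t, t - 0.5, model)
        assert compute_vgf(gf, t - 0.5).vgf == pytest.approx(0.3, abs=1e-8)

    def test_two_pixel_weighted_mean(self, tables):
        from glandfrac.gf import GFImage
        gf = GFImage(m1=np.array([0.0, 1.0]), m=np.array([0.0, 1.0]),
                     mask=np.array([True, True]), converged=np.array([True, True]),
                     sub_adipose=np.array([False, False]),
                     iterations=np.zeros(2, dtype=np.int32))
        res = compute_vgf(gf, np.array([1.0, 3.0]))
        assert res.vgf == pytest.approx(0.75)

    def test_truth_vgf_matches_analytic_volume_ratio(self, geom):
        """Ground-truth VGF from the rasters vs the phantom's exact
        glandular/breast volume ratio (half-cylinder geometry).  All rays
        touching the breast are counted: the chord sums then tile the
        volumes, margin rays included."""
        ph = build_phantom(4.0, 0.3)
        paths = trace_paths(ph, geom)
        from glandfrac.gf import GFImage
        touched = paths.t_breast > 0
        m = np.where(touched, paths.t_glandular / np.where(touched, paths.t_breast, 1.0), 0.0)
        gf = GFImage(m1=m, m=m, mask=touched, converged=touched,
                     sub_adipose=~touched, iterations=touched.astype(np.int32))
        vgf = compute_vgf(gf, paths.t_breast, touched).vgf
        v_gl = ph.glandular_height * np.pi * ph.glandular_radius**2 / 2
        v_breast = ph.thickness * np.pi * ph.outer_radius**2 / 2
        assert vgf == pytest.approx(v_gl / v_breast, rel=0.01)

    def test_empty_mask(self, tables):
        model = _model(tables)
        t = np.array([[4.5]])
        gf = ml_gf(np.array([[0.0]]), np.array([[3e4]]), t, t - 0.5, model)
        with pytest.raises(ValueError):
            compute_vgf(gf, t - 0.5)


class TestPipeline:
    def test_monochromatic_noiseless_recovery_is_exact(self, geom):
        """Scatter-free expectation-mode image at a single energy, inverted
        at that energy: per-pixel m equals the traced ground truth."""
        ph = build_phantom(4.0, 0.2)
        paths = trace_paths(ph, geom)
        mono = EnergySpectrum.monochromatic(21.0)
        img = simulate_projection(ph, geom, mono, 30000.0, spr_model=None,
                                  poisson=False, paths=paths)
        est = estimate_gf_from_sim(img, scatter_mode="skip", e_eff=21.0)
        inside = paths.mask & est.mask
        np.testing.assert_allclose(est.m[inside], paths.m_true[inside], atol=1e-6)

    def test_asg_skip_branch_records_no_scatter_step(self, geom, wal):
        from glandfrac.simulate import apply_asg
        ph = build_phantom(4.0, 0.2)
        img = apply_asg(simulate_projection(ph, geom, wal, 30000.0, seed=0), 0.75, seed=1)
        est = estimate_gf_from_sim(img, scatter_mode="skip",
                                   ref_glandular_fraction=0.2)
        assert est.meta["branch"] == "asg"
        assert est.meta["scatter_step_ran"] is False

    def test_gridless_branch_runs_both_steps_within_error_envelope(self, geom, wal):
        ph = build_phantom(4.0, 0.2)
        img = simulate_projection(ph, geom, wal, 30000.0, seed=2)
        est = estimate_gf_from_sim(img, ref_glandular_fraction=0.2)
        assert est.meta["scatter_step_ran"] is True
        interior = img.paths.glandular_interior(2) & est.mask
        err = est.m[interior] - img.paths.m_true[interior]
        assert abs(err.mean()) < 0.01
        assert np.sqrt((err**2).mean()) < 0.05

    def test_missing_thickness_raises(self, geom, wal):
        from glandfrac.gf import estimate_gf_pipeline
        with pytest.raises(ValueError):
            estimate_gf_pipeline(np.ones((4, 4)), np.ones((4, 4)), None, geom, wal)
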