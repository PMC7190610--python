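"""Stochastic sensitivity: Lyapunov solves, ellipses, cycle mu, bands."""

import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import bisect
from scipy.special import erf

import stoichswitch as sw
from stoichswitch.geometry import Separatrix
from stoichswitch.ssf import lyapunov_solve_3eq, periodic_scalar_solve

P_CIRCLE = 1.0 - np.exp(-0.5)   # makes the ellipse level exactly 1 at eps=1


class TestLyapunov:
    @pytest.mark.parametrize("F,G,expect", [
        (-np.eye(2), np.eye(2), np.diag([0.5, 0.5])),
        (np.diag([-1.0, -2.0]), np.diag([1.0, 2.0]), np.diag([0.5, 1.0])),
    ])
    def test_decoupled_closed_forms(self, F, G, expect):
        assert np.allclose(lyapunov_solve_3eq(F, G @ G.T), expect, atol=1e-14)

    def test_agrees_with_generic_solver(self, params3, stable3):
        for eq in stable3:
            ssf = sw.equilibrium_ssf(eq, params3)
            W_ref = solve_continuous_lyapunov(ssf.F, -ssf.S)
            assert np.abs(ssf.W - W_ref).max() < 1e-12

    def test_residual_and_definiteness(self, params3, params4, stable3):
        eqs = list(stable3) + [e for e in sw.interior_equilibria(params4)
                               if e.stability == "stable"]
        for eq, p in zip(eqs, (params3, params3, params4)):
            ssf = sw.equilibrium_ssf(eq, p)
            assert ssf.residual < 1e-10
            assert np.allclose(ssf.W, ssf.W.T)
            assert np.linalg.eigvalsh(ssf.W).min() > 0

    def test_rejects_unstable_equilibrium(self, params3, interior3):
        saddle = next(e for e in interior3 if e.stability == "saddle")
        with pytest.raises(ValueError, match="Hurwitz"):
            sw.equilibrium_ssf(saddle, params3)


class TestEllipse:
    def test_unit_circle_case(self, stable3):
        ell = sw.confidence_ellipse(np.zeros(2), np.eye(2),
                                    sw.ConfidenceSpec(P_CIRCLE, 1.0))
        assert ell.level == pytest.approx(1.0)
        assert np.allclose(np.linalg.norm(ell.boundary, axis=1), 1.0)
        assert ell.contains([(0.5, 0.5), (0.9, 0.9)]).tolist() == [True, False]

    def test_area_scales_with_noise_squared(self, params3, stable3):
        ssf = sw.equilibrium_ssf(stable3[1], params3)
        a1 = sw.confidence_ellipse(stable3[1], ssf, sw.ConfidenceSpec(0.95, 1e-3)).area
        a2 = sw.confidence_ellipse(stable3[1], ssf, sw.ConfidenceSpec(0.95, 2e-3)).area
        assert a2 / a1 == pytest.approx(4.0, rel=1e-12)

    def test_centered_on_equilibrium(self, params3, stable3):
        ssf = sw.equilibrium_ssf(stable3[0], params3)
        ell = sw.confidence_ellipse(stable3[0], ssf, sw.ConfidenceSpec(0.95, 1e-3))
        assert np.round(ell.center, 4).tolist() == [0.1603, 0.4415]

    def test_singular_W_rejected(self):
        with pytest.raises(ValueError):
            sw.confidence_ellipse(np.zeros(2), np.diag([1.0, 0.0]),
                                  sw.ConfidenceSpec(0.95, 1e-3))


def _vertical_line_separatrix(x0):
    pts = np.column_stack([np.full(200, x0), np.linspace(0.0, 1.0, 200)])
    return Separatrix(points=pts, saddle=pts[100],
                      stable_eigenvector=np.array([0.0, 1.0]),
                      box=(0.0, 1.0, 0.0, 1.0))


class TestTangency:
    def test_closed_form_distance(self):
        sep = _vertical_line_separatrix(0.1)
        eps = sw.tangency_threshold(np.zeros(2), np.eye(2), P_CIRCLE, sep)
        assert eps == pytest.approx(0.1, rel=1e-6)

    def test_monotone_in_fiducial_probability(self, params3, stable3, separatrix3):
        ssf = sw.equilibrium_ssf(stable3[0], params3)
        vals = [sw.tangency_threshold(stable3[0], ssf, P, separatrix3)
                for P in (0.5, 0.9, 0.95, 0.99)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_reference_magnitude(self, params3, stable3, separatrix3):
        # threshold for leaving the smaller-x basin: order 1e-3
        ssf = sw.equilibrium_ssf(stable3[0], params3)
        eps = sw.tangency_threshold(stable3[0], ssf, 0.95, separatrix3)
        assert 5e-4 < eps < 1e-2

    def test_center_on_separatrix_gives_zero(self, separatrix3, saddle3):
        assert sw.tangency_threshold(saddle3.location, np.eye(2), 0.95,
                                     separatrix3) == 0.0


class TestCycleSSF:
    def test_constant_coefficient_fixed_point(self):
        a0, b0 = -0.7, 0.3
        mu, A, res = periodic_scalar_solve(np.full(400, a0), np.full(400, b0), 5.0)
        assert np.allclose(mu, -b0 / a0, rtol=1e-12)
        assert A == pytest.approx(a0 * 5.0)
        assert res < 1e-12

    def test_normals_orthogonal_to_drift(self, cycle4, cssf4, params4):
        for z, p in zip(cycle4.samples[::100], cssf4.p[::100]):
            f = sw.drift(z, params4)
            assert abs(np.dot(p, f)) < 1e-12 * np.linalg.norm(f)
        assert np.allclose(np.linalg.norm(cssf4.p, axis=1), 1.0)

    def test_positive_and_periodic(self, cssf4):
        assert cssf4.mu.min() > 0
        assert cssf4.lyapunov_exponent < 0
        assert cssf4.periodicity_residual < 1e-8

    def test_resampling_invariance(self, params4, focus4, cssf4):
        fine = sw.cycle_ssf(sw.find_limit_cycle(params4, focus4, n_samples=4000),
                            params4)
        rel = np.abs(fine.mu[::2] - cssf4.mu) / cssf4.mu
        assert rel.max() < 1e-4

    def test_unstable_cycle_rejected(self):
        with pytest.raises(ValueError):
            periodic_scalar_solve(np.full(100, 0.2), np.full(100, 1.0), 2.0)

    def test_matches_weak_noise_transverse_variance(self, params4, cycle4, cssf4):
        # Monte-Carlo normal-deviation variance / eps^2 tracks mu(t) in the
        # weak-noise regime (eps = 1e-4; at larger eps this small near-Hopf
        # cycle leaves the Gaussian linearization regime)
        from scipy.spatial import cKDTree

        eps = 1e-4
        traj = sw.simulate(params4, sw.NoiseSpec(eps, eps), cycle4.samples[0],
                           4500.0, h=1e-3, seed=11)
        pts = traj.states[int(200 / 1e-3)::50]
        _, idx = cKDTree(cycle4.samples).query(pts)
        dev = np.einsum("ni,ni->n", pts - cycle4.samples[idx], cssf4.p[idx])
        N = len(cycle4.times)
        checked = 0
        for ph in range(0, N, N // 10):
            sel = np.abs(idx - ph) < N / 200
            if sel.sum() < 200:
                continue
            est = dev[sel].var() / eps**2
            assert est == pytest.approx(cssf4.mu[ph], rel=0.25)
            checked += 1
        assert checked >= 8


class TestBand:
    def test_erfinv_against_bisection(self, cycle4, cssf4):
        k = float(bisect(lambda x: erf(x) - 0.95, 0.0, 3.0, xtol=1e-12))
        band_k = sw.confidence_band(cycle4, cssf4,
                                    sw.ConfidenceSpec(0.95, 1e-4)).k
        assert band_k == pytest.approx(k, abs=1e-9)
        assert band_k == pytest.approx(1.385904, abs=5e-7)
        assert np.sqrt(2.0) * band_k == pytest.approx(1.959964, abs=5e-7)

    def test_width_linear_in_noise(self, cycle4, cssf4):
        w1 = sw.confidence_band(cycle4, cssf4,
                                sw.ConfidenceSpec(0.95, 1e-4)).half_width()
        w2 = sw.confidence_band(cycle4, cssf4,
                                sw.ConfidenceSpec(0.95, 2e-4)).half_width()
        assert np.allclose(w2, 2.0 * w1)

    def test_width_monotone_in_fiducial_probability(self, cycle4, cssf4):
        widths = [sw.confidence_band(cycle4, cssf4, sw.ConfidenceSpec(P, 1e-4))
                  .half_width().mean() for P in (0.75, 0.90, 0.95, 0.99)]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_boundaries_bracket_cycle(self, cycle4, cssf4):
        band = sw.confidence_band(cycle4, cssf4, sw.ConfidenceSpec(0.95, 1e-4))
        mid = 0.5 * (band.gamma1 + band.gamma2)
        assert np.abs(mid - cycle4.samples).max() < 1e-12
        assert band.contains(cycle4.samples[::100]).all()


class TestCoverage:
    def test_trivial_inside_outside(self, params3, stable3):
        ssf = sw.equilibrium_ssf(stable3[1], params3)
        ell = sw.confidence_ellipse(stable3[1], ssf, sw.ConfidenceSpec(0.95, 1e-3))
        center = np.tile(ell.center, (10, 1))
        assert sw.coverage_check(center, ell)["coverage"] == 1.0
        far = center + 1.0
        assert sw.coverage_check(far, ell)["coverage"] == 0.0
        with pytest.raises(ValueError):
            sw.coverage_check(np.empty((0, 2)), ell)
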