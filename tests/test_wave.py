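"""Dispersion relation, minimal wave speed, cubic root structure, and the
binding-rate optimization."""

import math

import numpy as np
import pytest

from reospread.params import VirusParams
from reospread.wave import (NoInvasionError, chi, minimal_wave_speed,
                            optimal_binding_rate, p3_coefficients, p3_roots,
                            positive_p3_root, rho_asymptote, speed_surface)


def _random_invading_params(rng):
    alpha = rng.uniform(0.01, 0.5)
    gamma = rng.uniform(0.05, 3.0)
    b_tilde = rng.uniform(150, 1500)
    return VirusParams(D_V=rng.uniform(0.002, 0.05), gamma_b=gamma,
                       alpha=alpha, nu=0.01, b_tilde=b_tilde)


class TestChi:
    def test_value_at_minimum_is_squared_speed(self, t3wt):
        d = minimal_wave_speed(t3wt)
        assert chi(d.rho_star, t3wt) == pytest.approx(d.c_star ** 2,
                                                      rel=1e-12)

    def test_zero_binding_reduces_to_linear(self, t3wt):
        p = t3wt.with_(gamma_b=0.0)
        for rho in (0.05, 0.3, 2.0):
            assert chi(rho, p) == pytest.approx(p.D_V * rho, rel=1e-12)

    def test_large_rho_slope_is_diffusion_coefficient(self, t3wt):
        assert chi(1e8, t3wt) / 1e8 == pytest.approx(t3wt.D_V, rel=1e-6)

    def test_pole_side_rejected(self, t3wt):
        rv = rho_asymptote(t3wt)
        with pytest.raises(ValueError, match="asymptote"):
            chi(rv * 0.5, t3wt)


class TestRhoAsymptote:
    def test_quadratic_oracle(self, t3wt):
        """rho_v equals the positive root of the denominator quadratic."""
        rv = rho_asymptote(t3wt)
        assert rv == pytest.approx(0.1880, abs=5e-5)
        coeffs = [1.0, t3wt.alpha + t3wt.gamma_b,
                  -t3wt.alpha * t3wt.gamma_b * (t3wt.R_V - 1.0)]
        pos = [r for r in np.roots(coeffs) if r > 0]
        assert rv == pytest.approx(pos[0], abs=1e-10)

    def test_infinite_binding_limit(self, t3wt):
        limit = t3wt.alpha * (t3wt.R_V - 1.0)
        assert rho_asymptote(t3wt.with_(gamma_b=1e6)) \
            == pytest.approx(limit, rel=1e-4)

    def test_subcritical_replication_rejected(self, t3wt):
        with pytest.raises(NoInvasionError):
            rho_asymptote(t3wt.with_(nu=0.001))


class TestMinimalWaveSpeed:
    def test_known_strains(self, t3wt, sv5):
        d1 = minimal_wave_speed(t3wt)
        assert d1.c_star == pytest.approx(0.04366, abs=5e-6)
        assert round(d1.lambda_star, 1) == 6.9
        d2 = minimal_wave_speed(sv5)
        assert d2.c_star == pytest.approx(0.05941, abs=5e-6)
        assert round(d2.lambda_star, 1) == 5.4

    def test_speed_vanishes_with_binding(self, t3wt):
        speeds = [minimal_wave_speed(t3wt.with_(gamma_b=g)).c_star
                  for g in (0.1, 0.01, 1e-3, 1e-4, 1e-5)]
        assert np.all(np.diff(speeds) < 0)
        assert speeds[-1] < 0.002

    def test_interior_minimum_conditions(self, t3wt, sv5):
        """chi'(rho*) = 0 and chi''(rho*) > 0 at every returned minimum."""
        for p in (t3wt, sv5):
            d = minimal_wave_speed(p)
            h = 1e-6 * d.rho_star
            c0, cp, cm = (chi(d.rho_star, p), chi(d.rho_star + h, p),
                          chi(d.rho_star - h, p))
            assert abs((cp - cm) / (2 * h)) < 1e-6
            assert (cp - 2 * c0 + cm) / h ** 2 > 0

    def test_leading_edge_determinant_vanishes(self, t3wt, sv5):
        """The 2x2 leading-edge matrix is singular at (c*, lambda*)."""
        for p in (t3wt, sv5):
            d = minimal_wave_speed(p)
            c, lam = d.c_star, d.lambda_star
            A = np.array([
                [-(c * lam + p.alpha), p.gamma_b * p.nu],
                [p.alpha * p.b_tilde,
                 p.D_V * lam ** 2 - c * lam - p.gamma_b]])
            assert abs(np.linalg.det(A)) < 1e-8

    def test_no_invasion_raises(self, t3wt):
        with pytest.raises(NoInvasionError):
            minimal_wave_speed(t3wt.with_(nu=0.0019))  # R_V < 1


class TestP3Roots:
    def test_unique_positive_root_matches_minimizer(self, t3wt):
        root = positive_p3_root(t3wt)
        assert root == pytest.approx(0.30, abs=5e-3)
        assert root == pytest.approx(minimal_wave_speed(t3wt).rho_star,
                                     abs=1e-6)

    def test_constant_term_negative(self, t3wt, sv5):
        for p in (t3wt, sv5):
            assert p3_coefficients(p)[3] < 0

    def test_one_positive_root_across_random_parameters(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = _random_invading_params(rng)
            roots = p3_roots(p)
            real = roots[np.abs(roots.imag) < 1e-9].real
            assert np.sum(real > 0) == 1


class TestOptimalBindingRate:
    @pytest.mark.parametrize("b_tilde, g_expect, c_expect", [
        (514, 0.29, 0.04858),
        (732, 0.42, 0.06002),
        (623, 0.36, 0.05460),
    ])
    def test_unconstrained_optima(self, t3wt, b_tilde, g_expect, c_expect):
        opt = optimal_binding_rate(t3wt.with_(b_tilde=b_tilde))
        assert round(opt.gamma_b_max, 2) == pytest.approx(g_expect, abs=0.01)
        assert opt.c_max == pytest.approx(c_expect, abs=5e-5)

    def test_range_capped_search(self, t3wt):
        """With the search capped at 0.5/h the b=1000 optimum hits the cap."""
        opt = optimal_binding_rate(t3wt.with_(b_tilde=1000),
                                   gamma_bounds=(0.15, 0.5))
        assert round(opt.gamma_b_max, 2) == 0.50
        assert opt.c_max == pytest.approx(0.07154, abs=5e-5)

    def test_binding_percent_consistency(self, t3wt):
        opt = optimal_binding_rate(t3wt)
        expected = 100.0 * (1.0 - math.exp(-opt.gamma_b_max))
        assert opt.binding_percent_1h == pytest.approx(expected, rel=1e-12)

    def test_maximum_is_interior(self, t3wt):
        """c* collapses at both binding extremes, so the optimum is interior."""
        opt = optimal_binding_rate(t3wt)
        lo = minimal_wave_speed(t3wt.with_(gamma_b=1e-4)).c_star
        hi = minimal_wave_speed(t3wt.with_(gamma_b=1e3)).c_star
        assert lo < 0.25 * opt.c_max
        assert hi < 0.25 * opt.c_max

    def test_speed_increases_with_burst_size(self, t3wt):
        speeds = [minimal_wave_speed(t3wt.with_(b_tilde=b)).c_star
                  for b in range(500, 1001, 100)]
        assert np.all(np.diff(speeds) > 0)


class TestSpeedSurface:
    def test_reference_cell(self, t3wt):
        rows = speed_surface([0.5], [1000.0], t3wt)
        assert rows[0]["c_star"] == pytest.approx(0.07154, abs=5e-5)

    def test_capped_sweep_row(self, t3wt):
        opt = optimal_binding_rate(t3wt.with_(b_tilde=750),
                                   gamma_bounds=(0.15, 0.5))
        assert round(opt.gamma_b_max, 2) == pytest.approx(0.43, abs=0.01)
        assert opt.c_max == pytest.approx(0.06090, abs=1e-4)

    def test_mean_optimal_ratio(self, t3wt):
        """gamma_b_max/b_tilde is nearly constant (~0.00056) over the sweep."""
        ratios = [optimal_binding_rate(t3wt.with_(b_tilde=b),
                                       gamma_bounds=(0.15, 0.5)).ratio
                  for b in range(500, 1001, 50)]
        assert np.mean(ratios) == pytest.approx(0.00056, abs=5e-5)

    def test_subcritical_cells_marked(self, t3wt):
        rows = speed_surface([0.5], [50.0], t3wt)  # R_V = 0.5 < 1
        assert rows[0]["invades"] is False and rows[0]["c_star"] is None
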