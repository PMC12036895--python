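"""Estimator unit and property tests: binding rate, diffusion, death rate,
burst size, replication number."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reospread.estimation import (BindingAssay, DiffusionColumnProfile,
                                  StokesEinsteinInput, TimeSeries,
                                  estimate_binding_rate, fit_burst_logistic,
                                  fit_death_rate, fit_diffusion_profile,
                                  half_life, stokes_einstein,
                                  viral_replication_number)
from reospread.params import VirusParams
from reospread.synthdata import (DEATH_ASSAY_TIMES, gen_burst_series,
                                 gen_death_series, gen_diffusion_fractions)


class TestBindingRate:
    @pytest.mark.parametrize("percents, expected", [
        ([80.64, 58.25, 45.99], 0.96),   # wild type replicates
        ([24.25, 34.10, 14.19], 0.28),   # weak-binding mutant replicates
    ])
    def test_replicated_assays(self, percents, expected):
        est = estimate_binding_rate(BindingAssay.from_percents(percents))
        assert est.point == pytest.approx(expected, abs=5e-3)

    def test_single_replicate_inverts_exponential_law(self):
        y = 1.0 - math.exp(-1.0)
        est = estimate_binding_rate(BindingAssay((y,), assay_duration=1.0))
        assert est.point == pytest.approx(1.0, abs=1e-12)

    @given(gamma=st.floats(0.01, 5.0), t=st.floats(0.1, 3.0),
           k=st.integers(1, 6))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_exactness(self, gamma, t, k):
        """Identical replicates from the forward law invert to gamma."""
        y = 1.0 - math.exp(-gamma * t)  # stays < 1 for gamma*t <= 15
        est = estimate_binding_rate(BindingAssay((y,) * k, assay_duration=t))
        assert est.point == pytest.approx(gamma, rel=1e-9)

    def test_monotone_in_added_replicate(self):
        base = (0.3, 0.5)
        g0 = estimate_binding_rate(BindingAssay(base)).point
        for y_new in (0.55, 0.7, 0.9):
            g1 = estimate_binding_rate(BindingAssay(base + (y_new,))).point
            assert g1 >= g0 or math.isclose(g1, g0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_degenerate_fraction_rejected(self, bad):
        with pytest.raises(ValueError, match="replicate"):
            BindingAssay((0.5, bad))

    def test_empty_assay_rejected(self):
        with pytest.raises(ValueError):
            BindingAssay(())


class TestHalfLife:
    @pytest.mark.parametrize("gamma, expected", [
        (0.96, 0.722), (0.28, 2.476), (math.log(2), 1.0),
    ])
    def test_values(self, gamma, expected):
        assert half_life(gamma) == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestDiffusionProfile:
    def test_noiseless_self_inversion(self):
        prof = gen_diffusion_fractions(D_V=0.01, t=120.0)
        d, v0, rss = fit_diffusion_profile(prof)
        assert d == pytest.approx(0.01, rel=5e-4)
        assert rss < 1e-6

    def test_recovery_under_multiplicative_noise(self):
        """Mean recovered D over 200 noisy columns within 5% of truth."""
        estimates = [
            fit_diffusion_profile(gen_diffusion_fractions(
                D_V=0.01, noise_sd=0.1, seed=seed))[0]
            for seed in range(1, 201)
        ]
        assert np.mean(estimates) == pytest.approx(0.01, rel=0.05)

    def test_all_zero_profile_rejected(self):
        prof = DiffusionColumnProfile((2.75, 8.25, 13.75), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="all-zero"):
            fit_diffusion_profile(prof)

    def test_percent_overflow_rejected(self):
        with pytest.raises(ValueError, match="100"):
            DiffusionColumnProfile((1.0, 2.0, 3.0), (60.0, 30.0, 20.0))


class TestStokesEinstein:
    def test_reference_virion(self):
        # 35 nm particle in water at 21 C
        inp = StokesEinsteinInput(temperature=294.15, viscosity=1e-3,
                                  particle_radius=35e-9)
        d = stokes_einstein(inp)
        assert d == pytest.approx(0.02, abs=5e-3)       # 1 s.f.
        assert d == pytest.approx(0.02217, abs=5e-5)    # 4 s.f., CODATA k_B

    def test_linear_in_inverse_radius(self):
        a = stokes_einstein(StokesEinsteinInput(294.15, 1e-3, 35e-9))
        b = stokes_einstein(StokesEinsteinInput(294.15, 1e-3, 70e-9))
        assert b == pytest.approx(a / 2.0, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            StokesEinsteinInput(0.0, 1e-3, 35e-9)


class TestDeathRate:
    T3WT_TABLE = TimeSeries(
        (15, 18, 24, 24, 24, 30, 30, 36, 36),
        (0.01470, 0.4015, 0.3438, 0.4679, 0.2899, 0.5864, 0.7808,
         0.6235, 0.8063))

    def test_printed_table_with_onset_delay(self):
        est = fit_death_rate(self.T3WT_TABLE, onset=15.0)
        assert est.point == pytest.approx(0.057, abs=0.02)
        assert est.extras["r_squared"] == pytest.approx(0.76, abs=0.05)

    def test_single_point_exact_inversion(self):
        series = TimeSeries((10.0, 10.0), (0.4, 0.4))
        est = fit_death_rate(series, onset=0.0)
        assert est.point == pytest.approx(-math.log(0.6) / 10.0, rel=1e-6)

    @pytest.mark.parametrize("alpha", [0.01, 0.057, 0.2, 0.5])
    def test_noiseless_exactness(self, alpha):
        series = gen_death_series(alpha, onset=0.0,
                                  times=(5, 10, 20, 30, 40))
        est = fit_death_rate(series, onset=0.0)
        assert est.point == pytest.approx(alpha, rel=1e-6)

    def test_recovery_under_noise(self):
        """Mean recovered alpha over 100 noisy assay designs within 10%."""
        estimates = [
            fit_death_rate(gen_death_series(0.057, onset=15.0,
                                            times=DEATH_ASSAY_TIMES,
                                            noise_sd=0.05, seed=s),
                           onset=15.0).point
            for s in range(100)
        ]
        assert np.mean(estimates) == pytest.approx(0.057, rel=0.10)

    def test_no_times_past_onset_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            fit_death_rate(TimeSeries((10.0,), (0.3,)), onset=15.0)


class TestBurstLogistic:
    def test_noiseless_recovery(self):
        series = gen_burst_series(K=514.0, rho=0.3, t_mid=18.0)
        fit = fit_burst_logistic(series)
        assert fit["carrying_capacity"] == pytest.approx(514.0, rel=1e-6)
        assert fit["growth_rate"] == pytest.approx(0.3, rel=1e-5)
        assert fit["midpoint"] == pytest.approx(18.0, rel=1e-5)

    def test_recovery_under_lognormal_noise(self):
        estimates = [
            fit_burst_logistic(gen_burst_series(
                K=732.0, noise_sd=0.2, seed=s))["carrying_capacity"]
            for s in range(100)
        ]
        assert np.mean(estimates) == pytest.approx(732.0, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_burst_logistic(TimeSeries((0, 10, 20), (1, 50, 400)))


class TestReplicationNumber:
    @pytest.mark.parametrize("b_tilde, expected", [(514, 5.14), (732, 7.32)])
    def test_observed_strains(self, b_tilde, expected):
        p = VirusParams(0.01, 0.5, 0.057, 0.01, b_tilde)
        rn = viral_replication_number(p)
        assert rn.value == pytest.approx(expected, rel=1e-12)
        assert not rn.dies_out

    def test_zero_infectivity_dies_out(self):
        p = VirusParams(0.01, 0.5, 0.057, 0.0, 514)
        rn = viral_replication_number(p)
        assert rn.value == 0.0 and rn.dies_out

    def test_matches_kinetic_determinant_threshold(self):
        """det A = alpha gamma (1 - R_V): zero exactly at R_V = 1."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            alpha = rng.uniform(0.01, 0.5)
            gamma = rng.uniform(0.05, 2.0)
            b_tilde = rng.uniform(50, 1500)
            p = VirusParams(0.01, gamma, alpha, 1.0 / b_tilde, b_tilde)
            A = np.array([[-alpha, gamma * p.nu],
                          [alpha * b_tilde, -gamma]])
            assert np.linalg.det(A) == pytest.approx(0.0, abs=1e-10)
            assert viral_replication_number(p).value == pytest.approx(1.0)
            # away from the threshold the determinant sign tracks 1 - R_V
            p2 = p.with_(nu=min(2.0 / b_tilde, 1.0))
            A2 = np.array([[-alpha, p2.gamma_b * p2.nu],
                           [alpha * b_tilde, -gamma]])
            assert np.sign(np.linalg.det(A2)) == np.sign(1.0 - p2.R_V)
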