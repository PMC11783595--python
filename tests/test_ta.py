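import numpy as np
import pytest

from oracles import ode_populations
from barrelfret.synth import NoiseSpec, default_ta_delays, fwhm_to_sigma, simulate_ta
from barrelfret.ta import (
    Kinetics,
    TAMap,
    TargetScheme,
    band_kinetics,
    compare_excitation,
    fit_target,
    heptamer_scheme,
    octamer_scheme,
    solve_populations,
)

IRF_SIGMA_PS = fwhm_to_sigma(0.28)


class TestTargetScheme:
    def test_time_constant_roundtrip(self):
        s = heptamer_scheme()
        assert s.tau_fast_ps == pytest.approx(10.4)
        assert 1.0 / s.k_slow == pytest.approx(0.98)
        assert 1.0 / s.k_donor == pytest.approx(15.9)
        assert 1.0 / s.k_acceptor == pytest.approx(4.9)

    def test_validation(self):
        with pytest.raises(ValueError):
            TargetScheme(-1.0, 1.0, 0.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            TargetScheme(1.0, 1.0, 1.5, 1.0, 1.0)


class TestSolvePopulations:
    def test_acceptor_excitation_is_irf_limited_step(self):
        # direct acceptor pumping: the band appears immediately (IRF-limited)
        delays = default_ta_delays()
        sch = TargetScheme.from_time_constants(10.4, 0.98, 15.9, 4.9, excited_species="acceptor")
        pops = solve_populations(sch, delays, IRF_SIGMA_PS)
        assert np.all(pops["donor"] == 0.0)
        ka = sch.k_acceptor * 1e-3
        from barrelfret.tcspc import exp_gauss

        np.testing.assert_allclose(
            pops["acceptor"], exp_gauss(delays, 1.0 / ka, IRF_SIGMA_PS), rtol=1e-12
        )

    def test_instant_transfer_matches_direct_excitation(self):
        delays = default_ta_delays()
        fast = TargetScheme.from_time_constants(1e-4, 0.98, 15.9, 4.9, f_fast=1.0)
        direct = TargetScheme.from_time_constants(10.4, 0.98, 15.9, 4.9, excited_species="acceptor")
        a_fast = solve_populations(fast, delays, IRF_SIGMA_PS)["acceptor"]
        a_direct = solve_populations(direct, delays, IRF_SIGMA_PS)["acceptor"]
        assert np.max(np.abs(a_fast - a_direct)) < 1e-3

    def test_all_rates_zero_gives_constant_after_time_zero(self):
        delays = default_ta_delays()
        sch = TargetScheme(0.0, 0.0, 0.6, 0.0, 0.0)
        pops = solve_populations(sch, delays, IRF_SIGMA_PS)
        late = delays > 5.0
        np.testing.assert_allclose(pops["donor"][late], 1.0, atol=1e-10)
        np.testing.assert_allclose(pops["acceptor"][late], 0.0, atol=1e-10)

    def test_degenerate_rates_removable_singularity(self):
        delays = default_ta_delays()
        # feeding rate exactly equals acceptor decay rate
        sch = TargetScheme.from_time_constants(10.0, 1.0, 1e9, 10.0 * 1e-3, f_fast=1.0)
        pops = solve_populations(sch, delays, IRF_SIGMA_PS)
        assert np.all(np.isfinite(pops["acceptor"]))
        ode = ode_populations(sch, delays, IRF_SIGMA_PS)
        assert np.max(np.abs(pops["acceptor"] - ode["acceptor"])) < 1e-5

    def test_matches_stiff_ode_for_default_heptamer(self):
        delays = default_ta_delays()
        ana = solve_populations(heptamer_scheme(), delays, IRF_SIGMA_PS)
        ode = ode_populations(heptamer_scheme(), delays, IRF_SIGMA_PS)
        for sp in ("donor", "acceptor"):
            assert np.max(np.abs(ana[sp] - ode[sp])) < 1e-6

    def test_population_conservation(self):
        # donor* + acceptor* + cumulative ground-state returns = excitation
        from scipy.integrate import cumulative_trapezoid

        delays = np.linspace(-1.0, 50.0, 20001)
        sch = heptamer_scheme()
        pops = solve_populations(sch, delays, IRF_SIGMA_PS)
        kd, ka = sch.k_donor * 1e-3, sch.k_acceptor * 1e-3
        returned = cumulative_trapezoid(
            kd * pops["donor"] + ka * pops["acceptor"], delays, initial=0.0
        )
        from scipy.stats import norm

        excitation = norm.cdf(delays / IRF_SIGMA_PS)
        total = pops["donor"] + pops["acceptor"] + returned
        assert np.max(np.abs(total - excitation)) < 1e-6


class TestBandKinetics:
    def test_constant_map_integrates_to_band_width_times_value(self):
        delays = np.array([-1.0, 0.0, 1.0, 2.0])
        wl = np.arange(560.0, 621.0, 1.0)
        tamap = TAMap(delays, wl, np.full((4, wl.size), 2.0))
        kin = band_kinetics(tamap, band=(575.0, 605.0))
        np.testing.assert_allclose(kin.signal, 2.0 * 30.0, rtol=1e-12)

    def test_zero_width_band_rejected(self):
        delays = np.array([-1.0, 1.0])
        wl = np.arange(560.0, 621.0, 1.0)
        tamap = TAMap(delays, wl, np.zeros((2, wl.size)))
        with pytest.raises(ValueError):
            band_kinetics(tamap, band=(590.0, 590.0))

    def test_band_outside_grid_rejected(self):
        delays = np.array([-1.0, 1.0])
        wl = np.arange(560.0, 621.0, 1.0)
        tamap = TAMap(delays, wl, np.zeros((2, wl.size)))
        with pytest.raises(ValueError):
            band_kinetics(tamap, band=(630.0, 660.0))

    def test_synthetic_heptamer_map_shows_delayed_negative_rise(self):
        tamap = simulate_ta(heptamer_scheme(), noise=NoiseSpec("gaussian", 0.0, 0))
        kin = band_kinetics(tamap)
        assert kin.signal.min() < 0  # stimulated emission is negative
        # the band magnitude keeps growing over the first few ps (delayed rise)
        i2 = np.searchsorted(kin.delays, 2.0)
        i20 = np.searchsorted(kin.delays, 20.0)
        assert abs(kin.signal[i20]) > abs(kin.signal[i2])


class TestFitTarget:
    def test_noiseless_roundtrip_recovers_fast_rate(self):
        tamap = simulate_ta(heptamer_scheme(), noise=NoiseSpec("gaussian", 0.0, 0))
        kin = band_kinetics(tamap)
        fit = fit_target(kin, heptamer_scheme(), irf_sigma=IRF_SIGMA_PS)
        assert fit.tau_fast_ps == pytest.approx(10.4, rel=1e-2)

    def test_scale_invariance(self):
        tamap = simulate_ta(heptamer_scheme(), noise=NoiseSpec("gaussian", 0.01, 4))
        kin = band_kinetics(tamap)
        fit1 = fit_target(kin, heptamer_scheme(), irf_sigma=IRF_SIGMA_PS)
        kin2 = Kinetics(kin.delays, 3.7 * kin.signal, band=kin.band)
        fit2 = fit_target(kin2, heptamer_scheme(), irf_sigma=IRF_SIGMA_PS)
        assert fit2.tau_fast_ps == pytest.approx(fit1.tau_fast_ps, rel=1e-6)
        assert fit2.amplitude == pytest.approx(3.7 * fit1.amplitude, rel=1e-6)

    def test_requires_pre_zero_baseline(self):
        kin = Kinetics(np.linspace(0.1, 100.0, 50), np.zeros(50))
        with pytest.raises(ValueError):
            fit_target(kin, heptamer_scheme(), irf_sigma=IRF_SIGMA_PS)

    def test_sub_irf_rate_flagged(self):
        truth = TargetScheme.from_time_constants(0.05, 0.98, 15.9, 4.9)
        tamap = simulate_ta(truth, noise=NoiseSpec("gaussian", 0.0, 0))
        kin = band_kinetics(tamap)
        fit = fit_target(kin, truth, irf_sigma=IRF_SIGMA_PS)
        assert "fast_rate_below_irf" in fit.flags


class TestCompareExcitation:
    def test_identical_traces_give_zero(self):
        delays = default_ta_delays()
        a = solve_populations(heptamer_scheme(), delays, IRF_SIGMA_PS)["acceptor"]
        kin = Kinetics(delays, -a)
        assert compare_excitation(kin, kin).delta_ps == 0.0

    def test_shifted_trace_recovers_shift(self):
        delays = np.linspace(-5.0, 200.0, 4001)
        direct = TargetScheme.from_time_constants(10.4, 0.98, 15.9, 4.9, excited_species="acceptor")
        a = solve_populations(direct, delays, IRF_SIGMA_PS)["acceptor"]
        shifted = solve_populations(direct, delays - 7.0, IRF_SIGMA_PS)["acceptor"]
        res = compare_excitation(Kinetics(delays, -shifted), Kinetics(delays, -a))
        assert res.delta_ps == pytest.approx(7.0, abs=0.2)

    def test_heptamer_pair_has_positive_delay_of_order_fast_time(self):
        delays = default_ta_delays()
        donor_pumped = solve_populations(heptamer_scheme(), delays, IRF_SIGMA_PS)["acceptor"]
        direct = TargetScheme.from_time_constants(10.4, 0.98, 15.9, 4.9, excited_species="acceptor")
        acc_pumped = solve_populations(direct, delays, IRF_SIGMA_PS)["acceptor"]
        res = compare_excitation(Kinetics(delays, -donor_pumped), Kinetics(delays, -acc_pumped))
        assert 2.0 < res.delta_ps < 30.0


def test_tamap_requires_pre_zero_delay():
    with pytest.raises(ValueError):
        TAMap(np.array([0.5, 1.0]), np.array([580.0, 590.0]), np.zeros((2, 2)))
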