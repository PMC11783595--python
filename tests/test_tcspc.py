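import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barrelfret.synth import NoiseSpec, simulate_tcspc
from barrelfret.tcspc import (
    DecayTrace,
    MultiExpModel,
    average_lifetime,
    convolve_model,
    exp_gauss,
    extract_fret_time,
    fit_reconvolution,
    select_model,
)

IRF_SIGMA = 0.170 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class TestExpGauss:
    def test_small_sigma_limit_is_shifted_exponential(self):
        t = np.linspace(0.0, 50.0, 5001)
        tau, t0 = 4.0, 2.0
        sigma = 1e-5
        got = exp_gauss(t, tau, sigma, t0)
        expected = np.where(t > t0, np.exp(-(t - t0) / tau), 0.0)
        mask = np.abs(t - t0) > 10 * sigma
        assert np.max(np.abs(got - expected)[mask]) < 1e-8

    def test_infinite_lifetime_is_gaussian_cdf(self):
        from scipy.stats import norm

        t = np.linspace(-1.0, 1.0, 401)
        got = exp_gauss(t, np.inf, 0.1, 0.0)
        np.testing.assert_allclose(got, norm.cdf(t / 0.1), rtol=1e-10, atol=1e-12)

    def test_no_overflow_for_tiny_sigma_long_lifetime(self):
        t = np.linspace(0.0, 100.0, 4096)
        out = exp_gauss(t, 15.9, 1e-3, 2.0)
        assert np.all(np.isfinite(out))

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            exp_gauss(np.arange(5.0), 1.0, 0.0)


class TestConvolveModel:
    def test_rise_plus_decay_sign_structure(self):
        t = np.linspace(0.0, 50.0, 2048)
        model = MultiExpModel([-1.0, 1.0], [0.98, 4.9], t0_shift=2.0)
        curve = convolve_model(model, t, IRF_SIGMA)
        assert curve[t < 1.0].max() < 1e-3  # ~0 before excitation
        peak_idx = np.argmax(curve)
        assert t[peak_idx] > 2.0  # delayed maximum: rises, then decays
        assert curve[-1] < curve[peak_idx]
        assert np.all(curve > -1e-9)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            MultiExpModel([1.0], [-1.0])
        with pytest.raises(ValueError):
            MultiExpModel([1.0, 1.0], [5.0, 1.0])  # not ascending
        with pytest.raises(ValueError):
            MultiExpModel([-1.0], [1.0])  # rise with no decay partner


class TestFitReconvolution:
    def test_noiseless_monoexponential_recovery(self):
        model = MultiExpModel([1.0], [15.9])
        trace = simulate_tcspc(model, noise=NoiseSpec("gaussian", 0.0, 0))
        fit = fit_reconvolution(trace, 1)
        assert fit.converged
        assert fit.model.lifetimes[0] == pytest.approx(15.9, rel=1e-4)

    def test_poisson_nile_red_lifetime_within_quoted_uncertainty(self):
        # direct-excitation acceptor lifetime 4.10 ns, 2e4 peak counts
        model = MultiExpModel([1.0], [4.10])
        trace = simulate_tcspc(model, t_max=50.0, noise=NoiseSpec("poisson", 0.0, 7))
        fit = fit_reconvolution(trace, 1)
        assert average_lifetime(fit.model) == pytest.approx(4.10, abs=0.2)

    def test_two_component_recovery_preserves_ordering(self):
        model = MultiExpModel([0.6, 0.4], [0.98, 15.9])
        trace = simulate_tcspc(model, noise=NoiseSpec("poisson", 0.0, 3))
        fit = fit_reconvolution(trace, 2)
        assert np.all(np.diff(fit.model.lifetimes) > 0)
        assert fit.model.lifetimes[0] == pytest.approx(0.98, abs=0.2)
        assert fit.model.lifetimes[1] == pytest.approx(15.9, abs=0.5)

    def test_reported_interval_coverage_band(self):
        # asymptotic-normality sanity: the +/-1 sigma interval should cover
        # truth roughly 68% of the time (60-75% band over 200 Poisson seeds)
        tau, hits, n = 5.0, 0, 200
        for s in range(n):
            trace = simulate_tcspc(
                MultiExpModel([1.0], [tau]),
                n_channels=1024,
                t_max=50.0,
                peak_counts=5000,
                noise=NoiseSpec("poisson", 0.0, 10_000 + s),
            )
            fit = fit_reconvolution(trace, 1, n_starts=2)
            hits += abs(fit.model.lifetimes[0] - tau) <= fit.param_errors["lifetimes"][0]
        assert 0.60 <= hits / n <= 0.75

    def test_rejects_too_many_components_for_trace(self):
        model = MultiExpModel([1.0], [5.0])
        trace = simulate_tcspc(model, n_channels=64, t_max=50.0, noise=NoiseSpec("poisson", 0.0, 0))
        with pytest.raises(ValueError):
            fit_reconvolution(trace, 4)


class TestAverageLifetime:
    def test_single_component(self):
        assert average_lifetime(MultiExpModel([2.0], [7.0])) == 7.0

    def test_intensity_vs_amplitude_weighting(self):
        model = MultiExpModel([1.0, 1.0], [2.0, 4.0])
        assert average_lifetime(model, "intensity") == pytest.approx(20.0 / 6.0, rel=1e-12)
        assert average_lifetime(model, "amplitude") == pytest.approx(3.0, rel=1e-12)

    def test_excludes_rise_components_and_bounds(self):
        model = MultiExpModel([-0.5, 1.0, 1.0], [0.5, 2.0, 4.0])
        avg = average_lifetime(model)
        assert 2.0 <= avg <= 4.0

    @given(
        st.lists(st.floats(0.1, 10.0), min_size=1, max_size=4),
        st.lists(st.floats(0.1, 30.0), min_size=4, max_size=4, unique=True),
    )
    @settings(max_examples=30, derandomize=True)
    def test_average_within_component_range(self, amps, taus):
        n = len(amps)
        taus = np.sort(np.asarray(taus[:n]))
        model = MultiExpModel(np.asarray(amps), taus)
        avg = average_lifetime(model)
        assert taus.min() - 1e-9 <= avg <= taus.max() + 1e-9


class TestSelectModel:
    def test_monoexponential_truth_selects_one(self):
        for s in range(5):
            trace = simulate_tcspc(
                MultiExpModel([1.0], [5.0]),
                n_channels=1024,
                t_max=50.0,
                peak_counts=10_000,
                noise=NoiseSpec("poisson", 0.0, 42 + s),
            )
            n, fits = select_model(trace, max_components=3)
            assert n == 1

    def test_separated_biexponential_selects_two(self):
        for s in range(3):
            trace = simulate_tcspc(
                MultiExpModel([0.5, 0.5], [1.5, 15.0]),
                n_channels=2048,
                t_max=80.0,
                peak_counts=20_000,
                noise=NoiseSpec("poisson", 0.0, 77 + s),
            )
            n, _ = select_model(trace, max_components=3)
            assert n == 2

    def test_pure_background_flagged(self):
        trace = simulate_tcspc(
            MultiExpModel([0.0], [5.0]),
            n_channels=1024,
            t_max=50.0,
            noise=NoiseSpec("poisson", 0.0, 5),
        )
        n, fits = select_model(trace, max_components=2)
        assert n == 1
        assert "amplitude_near_zero" in fits[n].flags


class TestExtractFretTime:
    @pytest.mark.parametrize("tau_rise,tau_decay", [(0.98, 4.9), (1.3, 5.1)])
    def test_recovers_rise_constant(self, tau_rise, tau_decay):
        vals = []
        for s in range(5):
            trace = simulate_tcspc(
                MultiExpModel([-0.15, 1.0], [tau_rise, tau_decay]),
                t_max=50.0,
                noise=NoiseSpec("poisson", 0.0, 100 + s),
            )
            res = extract_fret_time(trace, tau_decay)
            assert res.resolvable
            vals.append(res.tau_rise)
        assert np.mean(vals) == pytest.approx(tau_rise, abs=0.2)

    def test_no_rise_truth_reports_unresolvable(self):
        trace = simulate_tcspc(
            MultiExpModel([1.0], [4.9]), t_max=50.0, noise=NoiseSpec("poisson", 0.0, 11)
        )
        res = extract_fret_time(trace, 4.9)
        assert not res.resolvable
        assert res.tau_rise is None

    def test_amplitude_ratio_recovered(self):
        trace = simulate_tcspc(
            MultiExpModel([-0.15, 1.0], [0.98, 4.9]),
            t_max=50.0,
            noise=NoiseSpec("poisson", 0.0, 21),
        )
        res = extract_fret_time(trace, 4.9)
        assert res.amplitude_ratio == pytest.approx(0.15, abs=0.03)


def test_decay_trace_validation():
    t = np.arange(10.0)
    with pytest.raises(ValueError):
        DecayTrace(t, -np.ones(10), np.ones(10), 1.0)
    with pytest.raises(ValueError):
        DecayTrace(t, np.ones(10), np.ones(9), 1.0)
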