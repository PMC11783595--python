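import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bound_fraction_root, competitive_dye_signal
from barrelfret.spectra import Spectrum
from barrelfret.steady_state import (
    apparent_fret_efficiency,
    detect_displacement,
    fit_binding,
    screen_panel,
    unmix_spectrum,
)
from barrelfret.synth import (
    BindingSeries,
    DEFAULT_TITRATION_GRID,
    NoiseSpec,
    bound_fraction,
    default_screen_panels,
    simulate_titration,
)


def gauss_spectrum(grid, center, width, height=1.0):
    return Spectrum(grid, height * np.exp(-0.5 * ((grid - center) / width) ** 2))


class TestUnmix:
    def test_single_reference_identity(self):
        grid = np.arange(400.0, 700.0, 1.0)
        ref = gauss_spectrum(grid, 500.0, 20.0)
        res = unmix_spectrum(ref, [ref])
        assert res.coefficients[0] == pytest.approx(1.0, rel=1e-9)
        assert res.residual_norm < 1e-9

    def test_orthogonal_supports_separate_exactly(self):
        grid = np.arange(400.0, 700.0, 1.0)
        a = gauss_spectrum(grid, 440.0, 8.0)
        b = gauss_spectrum(grid, 650.0, 8.0)
        mixed = Spectrum(grid, 0.3 * a.values + 0.7 * b.values)
        res = unmix_spectrum(mixed, [a, b])
        np.testing.assert_allclose(res.coefficients, [0.3, 0.7], rtol=1e-8)

    def test_overlapping_mixture_matches_constrained_solver_oracle(self):
        from scipy.optimize import lsq_linear

        grid = np.arange(400.0, 700.0, 0.5)
        a = gauss_spectrum(grid, 500.0, 30.0)
        b = gauss_spectrum(grid, 540.0, 35.0)
        mixed = Spectrum(grid, 0.45 * a.values + 0.55 * b.values)
        res = unmix_spectrum(mixed, [a, b])
        A = np.column_stack([a.values, b.values])
        oracle = lsq_linear(A, mixed.values, bounds=(0, np.inf), tol=1e-14).x
        np.testing.assert_allclose(res.coefficients, oracle, atol=1e-6)

    def test_collinear_references_flagged(self):
        grid = np.arange(400.0, 700.0, 1.0)
        a = gauss_spectrum(grid, 500.0, 20.0)
        b = Spectrum(grid, 2.0 * a.values)
        with pytest.warns(UserWarning):
            res = unmix_spectrum(a, [a, b])
        assert res.collinear


class TestApparentFretEfficiency:
    @pytest.fixture()
    def panel(self, dye_spectra):
        d_em, _, a_em, _ = dye_spectra
        return d_em, a_em

    def test_donor_only_mixture_gives_zero(self, panel):
        d, a = panel
        assert apparent_fret_efficiency(d, a, d) == pytest.approx(0.0, abs=1e-9)

    def test_pure_acceptor_emission_gives_one(self, panel):
        d, a = panel
        assert apparent_fret_efficiency(d, a, a) == pytest.approx(1.0, abs=1e-6)

    def test_known_transfer_fraction_recovered(self, panel):
        d, a = panel
        mixed = Spectrum(d.wavelengths, 0.4 * d.values + 0.6 * a.values)
        assert apparent_fret_efficiency(d, a, mixed) == pytest.approx(0.6, abs=0.02)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, derandomize=True)
    def test_invariant_to_uniform_rescaling(self, scale):
        grid = np.arange(380.0, 720.0, 1.0)
        d = gauss_spectrum(grid, 450.0, 20.0)
        a = gauss_spectrum(grid, 593.0, 22.0)
        mixed = Spectrum(grid, 0.5 * d.values + 0.5 * a.values)
        e0 = apparent_fret_efficiency(d, a, mixed)
        ds = Spectrum(grid, scale * d.values)
        as_ = Spectrum(grid, scale * a.values)
        ms = Spectrum(grid, scale * mixed.values)
        assert apparent_fret_efficiency(ds, as_, ms) == pytest.approx(e0, rel=1e-9)

    def test_direct_excitation_subtracted(self, panel):
        d, a = panel
        # mixture contains 10% direct acceptor excitation on top of transfer
        mixed = Spectrum(d.wavelengths, 0.5 * d.values + 0.6 * a.values)
        e_corr = apparent_fret_efficiency(d, a, mixed, direct_excitation_fraction=0.1)
        e_raw = apparent_fret_efficiency(d, a, mixed)
        assert e_corr < e_raw


class TestScreenPanel:
    def test_default_fixture_finds_ten_positives(self):
        panels, positives = default_screen_panels(seed=0)
        results = screen_panel(panels)
        found = {r.peptide_id for r in results if r.positive}
        assert found == positives
        assert len(found) == 10

    def test_ranking_is_permutation_and_sorted(self):
        panels, _ = default_screen_panels(seed=1)
        results = screen_panel(panels)
        assert sorted(r.peptide_id for r in results) == sorted(p[0] for p in panels)
        e = [r.e_app for r in results]
        assert e == sorted(e, reverse=True)

    def test_null_panels_give_zero_positives(self, dye_spectra):
        d_em, _, a_em, _ = dye_spectra
        panels = [(f"N{i}", d_em, a_em, d_em) for i in range(4)]
        results = screen_panel(panels)
        assert sum(r.positive for r in results) == 0

    def test_full_transfer_panel_ranks_first(self, dye_spectra):
        d_em, _, a_em, _ = dye_spectra
        mixed = Spectrum(d_em.wavelengths, 0.5 * d_em.values + 0.5 * a_em.values)
        panels = [("LOW", d_em, a_em, d_em), ("TOP", d_em, a_em, a_em), ("MID", d_em, a_em, mixed)]
        results = screen_panel(panels)
        assert results[0].peptide_id == "TOP"
        assert results[0].positive

    def test_duplicate_ids_rejected(self, dye_spectra):
        d_em, _, a_em, _ = dye_spectra
        with pytest.raises(ValueError):
            screen_panel([("A", d_em, a_em, d_em), ("A", d_em, a_em, d_em)])


class TestBoundFraction:
    @pytest.mark.parametrize("p", [0.5, 2.0, 10.0, 30.0])
    def test_matches_root_finding_oracle(self, p):
        got = bound_fraction(np.array([p]), 0.5, 2.0)[0]
        assert got == pytest.approx(bound_fraction_root(p, 0.5, 2.0), rel=1e-10)

    def test_quoted_example(self):
        # Kd 2 uM, ligand 0.5 uM, peptide 30 uM
        got = bound_fraction(np.array([30.0]), 0.5, 2.0)[0]
        assert got == pytest.approx(bound_fraction_root(30.0, 0.5, 2.0), rel=1e-12)

    def test_no_binding_limit(self):
        frac = bound_fraction(DEFAULT_TITRATION_GRID, 0.5, 1e9)
        assert np.all(frac < 1e-6)


class TestFitBinding:
    def test_noiseless_roundtrip_machine_precision(self):
        series = simulate_titration(2.0, noise=NoiseSpec("gaussian", 0.0, 0))
        fit = fit_binding(series)
        assert fit.kd == pytest.approx(2.0, abs=1e-3)
        assert fit.identifiable

    def test_flat_series_flagged_unidentifiable(self):
        grid = DEFAULT_TITRATION_GRID
        series = BindingSeries(grid, np.full_like(grid, 0.5))
        fit = fit_binding(series)
        assert not fit.identifiable

    def test_mean_kd_recovery_under_noise(self):
        # 3 replicates, 2% gaussian noise, Kd = 5 uM: unbiased within 5%
        kds = [
            fit_binding(simulate_titration(5.0, noise=NoiseSpec("gaussian", 0.02, s), replicates=3)).kd
            for s in range(50)
        ]
        assert abs(np.mean(kds) / 5.0 - 1.0) < 0.05

    def test_requires_zero_and_enough_points(self):
        series = BindingSeries(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), np.ones(5))
        with pytest.raises(ValueError):
            fit_binding(series)


class TestDetectDisplacement:
    def test_identical_series_not_displaced(self):
        s = simulate_titration(2.0, noise=NoiseSpec("gaussian", 0.0, 0))[0]
        assert detect_displacement(s, s) == "not_displaced"

    def test_strong_plateau_drop_displaced(self):
        s = simulate_titration(2.0, noise=NoiseSpec("gaussian", 0.0, 0))[0]
        comp = BindingSeries(s.peptide_conc, 0.1 * s.f_norm, ligand_total=s.ligand_total)
        assert detect_displacement(s, comp) == "displaced"

    def test_mismatched_grids_rejected(self):
        s = simulate_titration(2.0)[0]
        other = BindingSeries(s.peptide_conc * 2.0, s.f_norm)
        with pytest.raises(ValueError):
            detect_displacement(s, other)

    def test_competitive_equilibrium_oracle_fixture(self):
        # a tight-binding competitor (Kd 0.01 uM) in excess of the sites
        # (100 uM vs <= 30 uM peptide) strips the dye (Kd 2 uM) off:
        # mass-action equilibrium oracle
        grid = DEFAULT_TITRATION_GRID
        single = BindingSeries(grid, bound_fraction(grid, 0.5, 2.0))
        with_comp = BindingSeries(
            grid, competitive_dye_signal(grid, 0.5, 100.0, 2.0, 0.01)
        )
        assert detect_displacement(single, with_comp) == "displaced"
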