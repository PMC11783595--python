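"""Seeded generators for every input the analysis pipeline consumes.

These stand in for the instruments: a TCSPC card with a 170 ps (FWHM)
Gaussian IRF and Poisson counting statistics, a pump–probe spectrometer with
a 280 fs IRF, a fluorimeter titration (single-site binding with ligand
depletion), metadynamics free-energy profiles over the inter-dye distance,
and 365 nm irradiation time courses for anthracene photodimerization.

Every generator is a pure function of its inputs and seed: identical calls
give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from . import ta as ta_mod
from .spectra import DPH, NILE_RED, FluorophoreSpec, Spectrum, make_spectra
from .tcspc import DecayTrace, MultiExpModel, convolve_model
from .ta import TAMap, TargetScheme, solve_populations

__all__ = [
    "NoiseSpec",
    "fwhm_to_sigma",
    "simulate_tcspc",
    "default_ta_delays",
    "default_ta_spectra",
    "simulate_ta",
    "BindingSeries",
    "bound_fraction",
    "simulate_titration",
    "FreeEnergyProfile",
    "simulate_fes",
    "heptamer_fes",
    "octamer_fes",
    "TimeCourse",
    "simulate_photolysis",
    "default_screen_panels",
]

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm * FWHM_TO_SIGMA


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: 'poisson' (counting) or 'gaussian' with relative std."""

    kind: str = "poisson"
    sigma: float = 0.0  # relative std, gaussian only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "gaussian"):
            raise ValueError("noise kind must be 'poisson' or 'gaussian'")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_tcspc(
    model: MultiExpModel,
    irf_fwhm: float = 0.170,
    n_channels: int = 4096,
    t_max: float = 100.0,
    peak_counts: int = 20_000,
    noise: NoiseSpec = NoiseSpec(),
    background_fraction: float = 0.01,
    t_zero: float = 2.0,
) -> DecayTrace:
    """Simulate a TCSPC histogram plus its IRF trace.

    The expected curve is the model convolved with a Gaussian IRF, scaled so
    its maximum equals ``peak_counts``, on top of a constant background
    (default 1% of peak). Counts are drawn channelwise (Poisson by default).
    If the window is shorter than 5× the longest decay lifetime, the trace is
    flagged with ``window_warning``.
    """
    if peak_counts < 100:
        raise ValueError("peak_counts must be >= 100")
    dt = t_max / n_channels
    t = (np.arange(n_channels) + 0.5) * dt
    sigma = fwhm_to_sigma(irf_fwhm)

    shifted = MultiExpModel(
        model.amplitudes, model.lifetimes, baseline=0.0, t0_shift=t_zero + model.t0_shift
    )
    mu0 = convolve_model(shifted, t, sigma)
    mmax = mu0.max()
    scale = peak_counts / mmax if mmax > 0 else 0.0
    background = background_fraction * peak_counts + model.baseline
    expected = np.maximum(mu0 * scale + background, 0.0)

    irf_expected = peak_counts * np.exp(-0.5 * ((t - t_zero - model.t0_shift) / sigma) ** 2)

    rng = noise.rng()
    if noise.kind == "poisson":
        counts = rng.poisson(expected).astype(float)
        irf_counts = rng.poisson(irf_expected).astype(float)
    else:
        ref = expected.max()
        counts = np.maximum(expected + rng.normal(0.0, noise.sigma * ref, t.shape), 0.0)
        irf_counts = np.maximum(
            irf_expected + rng.normal(0.0, noise.sigma * peak_counts, t.shape), 0.0
        )

    pos = model.amplitudes > 0
    longest = model.lifetimes[pos].max() if pos.any() else 0.0
    return DecayTrace(
        time=t,
        counts=counts,
        irf_counts=irf_counts,
        channel_width=dt,
        window_warning=bool(t_max < 5.0 * longest),
    )


def default_ta_delays(
    t_lin: float = 1.0, dt_lin: float = 0.05, t_max: float = 7000.0, n_log: int = 120
) -> np.ndarray:
    """Typical pump–probe delay grid: linear −1..+1 ps, then logarithmic to 7 ns."""
    lin = np.arange(-t_lin, t_lin, dt_lin)
    log = np.geomspace(t_lin, t_max, n_log)
    return np.unique(np.concatenate([lin, log]))


def default_ta_spectra(grid: np.ndarray | None = None) -> list[Spectrum]:
    """Stimulated-emission spectra (negative-valued) for donor and acceptor.

    The probe window covers the acceptor stimulated-emission band at 590 nm;
    the donor's stimulated emission sits far to the blue (DPH emits at
    430-480 nm), so only a weak tail of a donor feature at 510 nm reaches
    into the window.
    """
    if grid is None:
        grid = np.arange(500.0, 661.0, 2.0)
    donor_se = Spectrum(grid, -0.2 * np.exp(-0.5 * ((grid - 510.0) / 20.0) ** 2))
    acceptor_se = Spectrum(grid.copy(), -1.0 * np.exp(-0.5 * ((grid - 590.0) / 18.0) ** 2))
    return [donor_se, acceptor_se]


def simulate_ta(
    scheme: TargetScheme,
    species_spectra: list[Spectrum] | None = None,
    delays: np.ndarray | None = None,
    irf_fwhm: float = 0.28,
    noise: NoiseSpec = NoiseSpec("gaussian", 0.01, 0),
) -> TAMap:
    """Simulate a ΔmOD map from the two-population scheme.

    ΔmOD(delay, λ) = Σ_species population(delay) × spectrum(λ) + noise, with
    stimulated-emission spectra negative by convention. Gaussian noise sigma
    is relative to the absolute signal maximum.
    """
    if delays is None:
        delays = default_ta_delays()
    if species_spectra is None:
        species_spectra = default_ta_spectra()
    if len(species_spectra) != 2:
        raise ValueError("need exactly two species spectra (donor, acceptor)")
    if not np.array_equal(species_spectra[0].wavelengths, species_spectra[1].wavelengths):
        raise ValueError("species spectra must share a wavelength grid")

    sigma = fwhm_to_sigma(irf_fwhm)
    pops = solve_populations(scheme, delays, sigma)
    clean = np.outer(pops["donor"], species_spectra[0].values) + np.outer(
        pops["acceptor"], species_spectra[1].values
    )
    if noise.kind == "gaussian" and noise.sigma > 0:
        ref = np.abs(clean).max()
        clean = clean + noise.rng().normal(0.0, noise.sigma * ref, clean.shape)
    elif noise.kind == "poisson":
        raise ValueError("poisson noise is not meaningful for ΔmOD maps")
    return TAMap(delays, species_spectra[0].wavelengths.copy(), clean)


@dataclass
class BindingSeries:
    """A saturation binding titration: normalized fluorescence vs peptide conc."""

    peptide_conc: np.ndarray  # uM
    f_norm: np.ndarray
    ligand_total: float = 0.5  # uM
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.peptide_conc = np.asarray(self.peptide_conc, dtype=float)
        self.f_norm = np.asarray(self.f_norm, dtype=float)
        if self.peptide_conc.shape != self.f_norm.shape:
            raise ValueError("grid and values must have matching shapes")
        if np.any(self.peptide_conc < 0):
            raise ValueError("concentrations must be nonnegative")


def bound_fraction(peptide: np.ndarray, ligand_total: float, kd: float) -> np.ndarray:
    """Single-site bound-ligand fraction with ligand depletion (quadratic root).

    Solves [PL] from mass balance: [PL] = ((P+L+Kd) − sqrt((P+L+Kd)² − 4PL))/2,
    returned as [PL]/L. Used instead of the hyperbolic approximation because
    ligand (~0.5 μM) and Kd (low μM) are comparable here.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    P = np.asarray(peptide, dtype=float)
    L = float(ligand_total)
    s = P + L + kd
    pl = 0.5 * (s - np.sqrt(s**2 - 4.0 * P * L))
    return pl / L


DEFAULT_TITRATION_GRID = np.array(
    [0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0]
)


def simulate_titration(
    kd: float,
    ligand_total: float = 0.5,
    peptide_grid: np.ndarray | None = None,
    f0: float = 0.05,
    noise: NoiseSpec = NoiseSpec("gaussian", 0.02, 0),
    replicates: int = 1,
) -> list[BindingSeries]:
    """Simulate replicate binding titrations, F/Fmax = f0 + (1−f0)·bound + noise."""
    if peptide_grid is None:
        peptide_grid = DEFAULT_TITRATION_GRID
    grid = np.asarray(peptide_grid, dtype=float)
    clean = f0 + (1.0 - f0) * bound_fraction(grid, ligand_total, kd)
    rng = noise.rng()
    out = []
    for r in range(replicates):
        if noise.kind == "gaussian":
            f = clean + rng.normal(0.0, noise.sigma, grid.shape)
        else:  # poisson noise on a normalized series: scale to synthetic counts
            counts = rng.poisson(np.maximum(clean, 0.0) * 1e4)
            f = counts / 1e4
        out.append(BindingSeries(grid.copy(), f, ligand_total=ligand_total, replicate_id=r))
    return out


@dataclass
class FreeEnergyProfile:
    """1D free-energy curve over the inter-dye distance, optional std band."""

    distance: np.ndarray  # Angstrom
    free_energy: np.ndarray  # kJ/mol
    std: np.ndarray | None = None  # kJ/mol

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.distance.shape != self.free_energy.shape:
            raise ValueError("distance and free_energy must have matching shapes")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("distance grid must be strictly increasing")
        if not np.all(np.isfinite(self.free_energy)):
            raise ValueError("free energies must be finite")
        if self.std is not None:
            self.std = np.asarray(self.std, dtype=float)
            if self.std.shape != self.distance.shape:
                raise ValueError("std must match the grid")


def simulate_fes(
    wells: list[tuple[float, float, float]],
    distance_range: tuple[float, float] = (1.5, 40.0),
    step: float = 0.1,
    noise_std: float = 1.0,
    seed: int = 0,
    knot_spacing: float = 2.0,
) -> FreeEnergyProfile:
    """Free-energy profile as a sum of negative Gaussian wells plus smooth noise.

    ``wells`` is a list of (center Å, depth kJ/mol, width Å); depths are
    magnitudes (a 93 kJ/mol well contributes −93 at its center). The noise is
    a smooth random curve (Gaussian-distributed knots every ``knot_spacing``
    Å joined by a cubic spline), emulating the slowly varying error band of a
    converged metadynamics estimate rather than point-wise scatter.
    """
    lo, hi = distance_range
    if hi <= lo:
        raise ValueError("invalid distance range")
    d = np.arange(lo, hi + 0.5 * step, step)
    F = np.zeros_like(d)
    for center, depth, width in wells:
        if not lo <= center <= hi:
            raise ValueError(f"well center {center} outside range {distance_range}")
        if width <= 0 or depth < 0:
            raise ValueError("well widths must be positive and depths nonnegative")
        F -= depth * np.exp(-0.5 * ((d - center) / width) ** 2)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        knots = np.arange(lo - knot_spacing, hi + 2 * knot_spacing, knot_spacing)
        F = F + CubicSpline(knots, rng.normal(0.0, noise_std, knots.shape))(d)
    return FreeEnergyProfile(d, F, std=np.full_like(d, noise_std))


def heptamer_fes(seed: int = 0, noise_std: float = 1.0) -> FreeEnergyProfile:
    """Heptamer fixture: deep wells at 3.5 Å (−93) and 10.0 Å (−92 kJ/mol)
    plus a shallow 20–30 Å shelf."""
    wells = [(3.5, 93.0, 0.8), (10.0, 92.0, 1.2), (22.0, 8.0, 2.0), (27.0, 6.0, 2.0)]
    return simulate_fes(wells, noise_std=noise_std, seed=seed)


def octamer_fes(seed: int = 0, noise_std: float = 1.0) -> FreeEnergyProfile:
    """Octamer fixture: one broad global minimum at 4.1 Å (−94.6 kJ/mol) and a
    shallow minimum near 20 Å."""
    wells = [(4.1, 94.6, 1.6), (20.0, 10.0, 2.5)]
    return simulate_fes(wells, noise_std=noise_std, seed=seed)


@dataclass
class TimeCourse:
    """Normalized fluorescence vs irradiation time (minutes)."""

    time: np.ndarray  # min
    f_norm: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f_norm = np.asarray(self.f_norm, dtype=float)
        if self.time.shape != self.f_norm.shape:
            raise ValueError("time and f_norm must have matching shapes")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")


def simulate_photolysis(
    mode: str,
    rate: float,
    duration: float = 30.0,
    n_points: int = 16,
    noise: NoiseSpec = NoiseSpec("gaussian", 0.02, 0),
    plateau: float = 0.02,
    label: str = "",
) -> TimeCourse:
    """Anthracene photolysis time course.

    'promoted' (encapsulated π-stacked pair): F(t) = plateau + (1−plateau)
    exp(−rate·t) with rate in 1/min. 'inhibited' (free or excluded
    anthracene): slow linear photobleach F(t) = 1 − rate·t, clipped at 0.
    """
    if mode not in ("promoted", "inhibited"):
        raise ValueError("mode must be 'promoted' or 'inhibited'")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.linspace(0.0, duration, n_points)
    if mode == "promoted":
        f = plateau + (1.0 - plateau) * np.exp(-rate * t)
    else:
        f = np.clip(1.0 - rate * t, 0.0, None)
    if noise.kind == "gaussian" and noise.sigma > 0:
        f = f + noise.rng().normal(0.0, noise.sigma, t.shape)
    return TimeCourse(t, f, label=label)


#: Ground-truth transfer fractions of the default 15-peptide screen fixture:
#: 10 FRET-positive barrels (the heptamer #1 strongest) and 5 negatives.
SCREEN_TRANSFER_FRACTIONS = {
    "P01": 0.85,
    "P02": 0.72,
    "P03": 0.02,
    "P04": 0.00,  # hexamer-like: binds both dyes, no transfer
    "P05": 0.55,
    "P06": 0.47,
    "P07": 0.40,
    "P08": 0.01,
    "P09": 0.34,
    "P10": 0.29,
    "P11": 0.00,
    "P12": 0.24,
    "P13": 0.65,
    "P14": 0.20,
    "P15": 0.02,
}


def default_screen_panels(
    seed: int = 0,
    noise_sigma: float = 0.01,
    donor: FluorophoreSpec = DPH,
    acceptor: FluorophoreSpec = NILE_RED,
):
    """The default 15-peptide ternary screen fixture.

    Returns ``(panels, positives)`` where each panel is
    ``(peptide_id, donor_only, acceptor_only, mixed)`` and ``positives`` is
    the set of peptide ids constructed with a nonzero transfer fraction
    (10 of 15). The mixed spectrum is (1−E)·donor + E·acceptor with
    multiplicative Gaussian noise on every spectrum.
    """
    grid = np.arange(380.0, 720.0, 1.0)
    rng = np.random.default_rng(seed)
    donor_ref, _ = make_spectra(donor, grid)
    acceptor_em = make_spectra(acceptor, grid)[0]

    def noisy(values):
        return np.maximum(values * (1.0 + rng.normal(0.0, noise_sigma, values.shape)), 0.0)

    panels = []
    for pid, e in SCREEN_TRANSFER_FRACTIONS.items():
        d = Spectrum(grid, noisy(donor_ref.values))
        a = Spectrum(grid, noisy(acceptor_em.values))
        mixed = Spectrum(
            grid, noisy((1.0 - e) * donor_ref.values + e * acceptor_em.values)
        )
        panels.append((pid, d, a, mixed))
    positives = {pid for pid, e in SCREEN_TRANSFER_FRACTIONS.items() if e >= 0.1}
    return panels, positives
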