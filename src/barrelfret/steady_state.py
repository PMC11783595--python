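"""Steady-state FRET screening, spectral unmixing, binding isotherms, and
competitive-displacement detection.

The screen statistic is an apparent FRET efficiency E_app built from a
ratiometric sensitized-acceptor readout: the mixed donor+acceptor emission
spectrum is unmixed against single-dye references, the sensitized acceptor
signal (acceptor coefficient × acceptor band area, corrected for direct
acceptor excitation) is compared with the residual donor signal, and

    E_app = sensitized / (sensitized + donor),

clamped to [0, 1]. Band areas integrate ±40 nm around the 450 nm donor and
593 nm acceptor reference peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, nnls

from .spectra import Spectrum
from .synth import BindingSeries, bound_fraction

__all__ = [
    "DONOR_BAND",
    "ACCEPTOR_BAND",
    "UnmixResult",
    "unmix_spectrum",
    "apparent_fret_efficiency",
    "ScreenResult",
    "screen_panel",
    "BindingFit",
    "fit_binding",
    "detect_displacement",
]

DONOR_BAND = (410.0, 490.0)  # 450 nm +/- 40
ACCEPTOR_BAND = (553.0, 633.0)  # 593 nm +/- 40


@dataclass
class UnmixResult:
    coefficients: np.ndarray
    residual_norm: float
    collinear: bool = False


def unmix_spectrum(mixed: Spectrum, references: list[Spectrum]) -> UnmixResult:
    """Nonnegative least-squares decomposition of a mixed spectrum.

    References are interpolated onto the mixed spectrum's grid. Degenerate
    (near-collinear) reference sets are flagged but still solved.
    """
    if len(references) < 1:
        raise ValueError("need at least one reference spectrum")
    grid = mixed.wavelengths
    A = np.column_stack([ref.interp(grid) for ref in references])
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError("a reference spectrum has no support on the mixed grid")
    collinear = bool(np.linalg.cond(A / norms) > 1e8)
    if collinear:
        warnings.warn("reference spectra are nearly collinear; coefficients ill-determined")
    coef, rnorm = nnls(A, mixed.values)
    return UnmixResult(coefficients=coef, residual_norm=float(rnorm), collinear=collinear)


def apparent_fret_efficiency(
    donor_only: Spectrum,
    acceptor_only: Spectrum,
    mixed: Spectrum,
    direct_excitation_fraction: float = 0.0,
) -> float:
    """Ratiometric apparent FRET efficiency from a three-spectrum panel.

    The mixed spectrum is unmixed against the single-dye references; the
    sensitized acceptor signal is the acceptor coefficient minus the direct
    acceptor-excitation fraction, times the acceptor-only band area. The
    result is invariant to uniform rescaling of all three spectra.
    """
    res = unmix_spectrum(mixed, [donor_only, acceptor_only])
    c_d, c_a = res.coefficients
    b_d = donor_only.band_area(*DONOR_BAND)
    b_a = acceptor_only.band_area(*ACCEPTOR_BAND)
    donor_signal = c_d * b_d
    sensitized = (c_a - direct_excitation_fraction) * b_a
    total = sensitized + donor_signal
    if total <= 0:
        if donor_signal <= 0 and sensitized <= 0:
            raise ValueError("zero total signal in both bands")
        return 0.0
    return float(np.clip(sensitized / total, 0.0, 1.0))


@dataclass
class ScreenResult:
    peptide_id: str
    e_app: float
    positive: bool
    donor_signal: float
    acceptor_signal: float


def screen_panel(
    panels: list[tuple],
    threshold: float = 0.1,
    direct_excitation_fraction: float = 0.0,
) -> list[ScreenResult]:
    """Rank a screen of (peptide_id, donor_only, acceptor_only, mixed) panels.

    Results are sorted by descending E_app (ties broken by lexical id);
    ``positive`` marks panels at or above the threshold (default 0.1).
    """
    if len(panels) < 1:
        raise ValueError("need at least one panel")
    ids = [p[0] for p in panels]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peptide_id in screen")
    results = []
    for pid, donor_only, acceptor_only, mixed in panels:
        res = unmix_spectrum(mixed, [donor_only, acceptor_only])
        c_d, c_a = res.coefficients
        e = apparent_fret_efficiency(
            donor_only, acceptor_only, mixed, direct_excitation_fraction
        )
        results.append(
            ScreenResult(
                peptide_id=pid,
                e_app=e,
                positive=bool(e >= threshold),
                donor_signal=float(c_d * donor_only.band_area(*DONOR_BAND)),
                acceptor_signal=float(c_a * acceptor_only.band_area(*ACCEPTOR_BAND)),
            )
        )
    return sorted(results, key=lambda r: (-r.e_app, r.peptide_id))


@dataclass
class BindingFit:
    """Single-site (ligand-depletion) binding fit."""

    kd: float  # uM
    f0: float
    fmax: float
    kd_err: float
    f0_err: float
    fmax_err: float
    reduced_chi2: float
    identifiable: bool
    converged: bool = True


def fit_binding(series) -> BindingFit:
    """Weighted least-squares fit of the quadratic single-site model.

    ``series`` may be a BindingSeries or a list of replicates sharing a
    concentration grid. The model is F = f0 + (fmax − f0) · bound_fraction(P;
    Kd, L_total). A Kd whose standard error exceeds the estimate is flagged
    unidentifiable (flat series).
    """
    if isinstance(series, BindingSeries):
        series = [series]
    grid = series[0].peptide_conc
    ltot = series[0].ligand_total
    for s in series[1:]:
        if not np.array_equal(s.peptide_conc, grid):
            raise ValueError("replicates must share the concentration grid")
    if np.unique(grid).size < 5 or grid.min() > 0:
        raise ValueError("need >= 5 distinct concentrations including 0")

    P = np.concatenate([s.peptide_conc for s in series])
    F = np.concatenate([s.f_norm for s in series])

    def model(p, kd, f0, fmax):
        return f0 + (fmax - f0) * bound_fraction(p, ltot, kd)

    half = np.interp(0.5 * (F.min() + F.max()), np.sort(F), P[np.argsort(F)])
    p0 = [max(float(half), 0.5), float(F[np.argmin(P)]), float(F.max())]
    try:
        popt, pcov = curve_fit(
            model,
            P,
            F,
            p0=p0,
            bounds=([1e-6, -1.0, -1.0], [1e4, 2.0, 5.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"binding fit did not converge (last p0={p0})") from exc
    perr = np.sqrt(np.abs(np.diag(pcov)))
    resid = F - model(P, *popt)
    dof = max(F.size - 3, 1)
    red = float(np.sum(resid**2) / dof)
    # unidentifiable when the Kd error swamps the estimate or the series is
    # flat (no binding amplitude to constrain Kd)
    identifiable = bool(
        np.isfinite(perr[0])
        and perr[0] < popt[0]
        and abs(popt[2] - popt[1]) > 1e-3
    )
    return BindingFit(
        kd=float(popt[0]),
        f0=float(popt[1]),
        fmax=float(popt[2]),
        kd_err=float(perr[0]),
        f0_err=float(perr[1]),
        fmax_err=float(perr[2]),
        reduced_chi2=red,
        identifiable=identifiable,
    )


def detect_displacement(
    single_dye: BindingSeries, with_competitor: BindingSeries, drop_threshold: float = 0.5
) -> str:
    """Classify competitive displacement from matched titrations.

    Compares the mean normalized fluorescence over the saturating region (top
    quartile of the concentration grid): 'displaced' if the competitor series
    falls below (1 − drop_threshold) × the single-dye series there.
    """
    if not np.array_equal(single_dye.peptide_conc, with_competitor.peptide_conc):
        raise ValueError("concentration grids must match")
    conc = single_dye.peptide_conc
    cut = np.quantile(conc, 0.75)
    sat = conc >= cut
    m1 = float(np.mean(single_dye.f_norm[sat]))
    m2 = float(np.mean(with_competitor.f_norm[sat]))
    return "displaced" if m2 < (1.0 - drop_threshold) * m1 else "not_displaced"
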