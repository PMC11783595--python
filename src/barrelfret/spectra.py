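"""Optical spectra on wavelength grids, and the fluorophores used throughout.

The donor/acceptor pair studied here is 1,6-diphenyl-1,3,5-hexatriene (DPH,
emitting around 450 nm with a vibronic progression) and Nile red (a broad
solvatochromic band near 593 nm in a hydrophobic channel). Spectra are held as
sampled curves on strictly increasing wavelength grids; emission spectra are
dimensionless shapes, extinction spectra carry absolute molar extinction in
M^-1 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "FluorophoreSpec",
    "make_spectra",
    "DPH",
    "NILE_RED",
]


@dataclass
class Spectrum:
    """A sampled optical spectrum.

    Parameters
    ----------
    wavelengths : array of float
        Wavelength grid in nm, strictly increasing.
    values : array of float
        Intensity (a.u.) for ``kind='emission'`` or molar extinction
        (M^-1 cm^-1) for ``kind='extinction'``.
    kind : {'emission', 'extinction'}
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.size == 0:
            raise ValueError("empty wavelength grid")
        if self.wavelengths.ndim != 1 or self.values.shape != self.wavelengths.shape:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind not in ("emission", "extinction"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "extinction" and np.any(self.values < 0):
            raise ValueError("extinction values must be nonnegative")

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid`` (nm); zero outside support."""
        return np.interp(grid, self.wavelengths, self.values, left=0.0, right=0.0)

    def area(self) -> float:
        """Integral over the full grid (trapezoid rule)."""
        return float(np.trapezoid(self.values, self.wavelengths))

    def band_area(self, lo: float, hi: float) -> float:
        """Integral over the band [lo, hi] nm, with linear interpolation at edges."""
        if hi <= lo:
            raise ValueError("band must have positive width")
        grid = np.union1d(self.wavelengths, [lo, hi])
        grid = grid[(grid >= lo) & (grid <= hi)]
        if grid.size < 2:
            return 0.0
        return float(np.trapezoid(self.interp(grid), grid))


@dataclass(frozen=True)
class FluorophoreSpec:
    """Gaussian-peak description of a fluorophore's emission and absorption.

    ``emission_peaks`` and ``extinction_peaks`` are lists of
    ``(center_nm, width_nm, height)`` tuples, where ``width`` is the Gaussian
    standard deviation. Emission heights are relative; extinction heights are
    peak molar extinction coefficients (M^-1 cm^-1).
    """

    name: str
    emission_peaks: tuple = ()
    extinction_peaks: tuple = ()
    quantum_yield: float = 1.0
    lifetime_ns: float = 1.0

    def __post_init__(self) -> None:
        for peaks in (self.emission_peaks, self.extinction_peaks):
            for center, width, height in peaks:
                if width <= 0:
                    raise ValueError("peak widths must be positive")
                if height < 0:
                    raise ValueError("peak heights must be nonnegative")
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum_yield must lie in [0, 1]")
        if self.lifetime_ns <= 0:
            raise ValueError("lifetime must be positive")


def _gaussian_sum(grid: np.ndarray, peaks) -> np.ndarray:
    out = np.zeros_like(grid, dtype=float)
    for center, width, height in peaks:
        out += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return out


def make_spectra(spec: FluorophoreSpec, grid: np.ndarray) -> tuple[Spectrum, Spectrum]:
    """Build (emission, extinction) spectra for a fluorophore on ``grid``.

    The emission spectrum is area-normalized (unit integral over the grid);
    the extinction spectrum is in absolute M^-1 cm^-1.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")

    em = _gaussian_sum(grid, spec.emission_peaks)
    area = np.trapezoid(em, grid)
    if area > 0:
        em = em / area
    ext = _gaussian_sum(grid, spec.extinction_peaks)
    return (
        Spectrum(grid, em, kind="emission"),
        Spectrum(grid.copy(), ext, kind="extinction"),
    )


# Default fluorophores. DPH shows a three-band vibronic progression around
# 450 nm and absorbs near 352 nm (the donor-selective excitation wavelength);
# Nile red in a hydrophobic channel emits a single broad band at 593 nm and
# absorbs around 545 nm with a tail overlapping DPH emission.
DPH = FluorophoreSpec(
    name="DPH",
    emission_peaks=((428.0, 12.0, 0.85), (452.0, 13.0, 1.0), (481.0, 16.0, 0.55)),
    extinction_peaks=((334.0, 12.0, 6.0e4), (352.0, 11.0, 8.0e4), (371.0, 12.0, 6.5e4)),
    quantum_yield=0.65,
    lifetime_ns=15.9,
)

NILE_RED = FluorophoreSpec(
    name="Nile red",
    emission_peaks=((593.0, 22.0, 1.0),),
    extinction_peaks=((545.0, 34.0, 4.5e4),),
    quantum_yield=0.7,
    lifetime_ns=4.1,
)
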