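"""Free-energy-profile post-processing: basin detection, Boltzmann
populations, and stacking-state classification.

Profiles are 1D free-energy curves over the donor–acceptor center-of-mass
distance (Å, kJ/mol), e.g. from well-tempered metadynamics along that
collective variable. This module only analyzes such profiles; it never runs
any sampling. Basins are prominence-filtered local minima with watershed
boundaries at the separating maxima; populations are Boltzmann integrals
∫ exp(−F/RT) dd over each basin, normalized over the returned basins.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synth import FreeEnergyProfile

__all__ = [
    "Basin",
    "find_basins",
    "boltzmann_populations",
    "classify_states",
    "read_profile",
    "GAS_CONSTANT_KJ",
]

#: R in kJ mol^-1 K^-1
GAS_CONSTANT_KJ = 8.314462618e-3

STACKED_MAX_A = 5.0  # fully pi-stacked
SLIPPED_MAX_A = 12.0  # slipped-stacked


@dataclass
class Basin:
    """A detected free-energy well."""

    position: float  # Angstrom
    depth: float  # kJ/mol, value at the minimum
    boundaries: tuple[float, float]  # Angstrom
    population: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.boundaries
        if not lo <= self.position <= hi:
            raise ValueError("boundaries must contain the basin position")


def find_basins(profile: FreeEnergyProfile, min_prominence: float = 2.0) -> list[Basin]:
    """Local minima with prominence >= ``min_prominence`` (kJ/mol).

    Boundaries between adjacent basins sit at the separating maximum
    (watershed); the outermost boundaries are the profile ends. A monotone
    profile yields an empty list. Adding a constant to the profile changes
    nothing.
    """
    d, F = profile.distance, profile.free_energy
    if d.size < 10:
        raise ValueError("profile too short (need >= 10 grid points)")
    idx, _ = find_peaks(-F, prominence=min_prominence)
    if idx.size == 0:
        return []
    bounds = [d[0]]
    for a, b in zip(idx[:-1], idx[1:]):
        sep = a + int(np.argmax(F[a : b + 1]))
        bounds.append(d[sep])
    bounds.append(d[-1])
    return [
        Basin(position=float(d[i]), depth=float(F[i]), boundaries=(float(lo), float(hi)))
        for i, lo, hi in zip(idx, bounds[:-1], bounds[1:])
    ]


def boltzmann_populations(
    profile: FreeEnergyProfile, basins: list[Basin], temperature: float = 298.0
) -> np.ndarray:
    """Per-basin Boltzmann fractions at ``temperature`` (K).

    The profile is shifted so its global minimum is zero before
    exponentiation (overflow guard). Fractions are normalized over the given
    basins and also stored on each Basin.
    """
    if not basins:
        raise ValueError("empty basin list")
    d, F = profile.distance, profile.free_energy
    rt = GAS_CONSTANT_KJ * temperature
    w = np.exp(-(F - F.min()) / rt)
    weights = []
    for b in basins:
        lo, hi = b.boundaries
        mask = (d >= lo) & (d <= hi)
        if mask.sum() < 2:
            weights.append(0.0)
            continue
        weights.append(float(np.trapezoid(w[mask], d[mask])))
    weights = np.asarray(weights)
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total Boltzmann weight over basins")
    fractions = weights / total
    for b, f in zip(basins, fractions):
        b.population = float(f)
    return fractions


def classify_states(basins: list[Basin]) -> list[str]:
    """Label basins by dye-pair geometry: 'stacked' (<= 5 Å, fully π-stacked),
    'slipped' (<= 12 Å, slipped-stacked), else 'distal'."""
    labels = []
    for b in basins:
        if b.position <= STACKED_MAX_A:
            labels.append("stacked")
        elif b.position <= SLIPPED_MAX_A:
            labels.append("slipped")
        else:
            labels.append("distal")
    return labels


def read_profile(path) -> FreeEnergyProfile:
    """Read a free-energy profile from CSV or whitespace-delimited text.

    Accepts the package's CSV dialect (header ``distance_A,
    free_energy_kJ_mol[, std_kJ_mol]``) and the common two/three-column
    whitespace FES dump format (``#`` comments allowed, no header). The
    dialect is auto-detected.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"no data in {path}")
    first = lines[0]
    sep = "," if "," in first else r"\s+"
    has_header = any(c.isalpha() for c in first.replace("e", "").replace("E", ""))
    df = pd.read_csv(
        _io.StringIO("\n".join(lines)),
        sep=sep,
        header=0 if has_header else None,
        engine="python",
    )
    if df.shape[1] < 2:
        raise ValueError("profile file must have at least two columns")
    cols = df.to_numpy(dtype=float).T
    std = cols[2] if df.shape[1] >= 3 else None
    return FreeEnergyProfile(cols[0], cols[1], std=std)
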