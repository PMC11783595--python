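"""Independent oracles used by the test suite.

Each routine recomputes a quantity by a route deliberately different from the
implementation it checks: discrete FFT convolution instead of the analytic
exponential⊗Gaussian, stiff ODE integration instead of closed-form target
populations, exhaustive grid scanning instead of prominence-based peak
finding, scalar root finding instead of the quadratic binding formula, and
dense Riemann summation instead of union-grid trapezoid quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import fftconvolve


def fft_exp_gauss(t: np.ndarray, tau: float, sigma: float, t0: float = 0.0) -> np.ndarray:
    """Exponential⊗Gaussian by discrete FFT convolution on the given grid.

    The grid must be uniform and fine relative to sigma. The sample at the
    step discontinuity is set to 1/2 (trapezoid-consistent sampling), so the
    discrete sum converges at second order in the step size.
    """
    dt = t[1] - t[0]
    f = np.where(t > t0, np.exp(-(t - t0) / tau), 0.0)
    on_jump = np.isclose(t, t0, atol=dt * 1e-6)
    f = np.where(on_jump, 0.5, f)
    n_half = int(np.ceil(8.0 * sigma / dt))
    tg = np.arange(-n_half, n_half + 1) * dt
    kernel = np.exp(-0.5 * (tg / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    return fftconvolve(f, kernel, mode="same") * dt


def ode_populations(scheme, delays: np.ndarray, sigma: float) -> dict[str, np.ndarray]:
    """Two-population scheme populations by stiff ODE integration.

    The Gaussian IRF enters as the excitation source term; integration starts
    well before time zero with empty excited states.
    """
    kf = scheme.k_fast
    ks = scheme.k_slow * 1e-3
    kd = scheme.k_donor * 1e-3
    ka = scheme.k_acceptor * 1e-3
    f = scheme.f_fast
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))

    def g(t):
        return norm * np.exp(-0.5 * (t / sigma) ** 2)

    if scheme.excited_species == "acceptor":

        def rhs(t, y):
            return [g(t) - ka * y[0]]

        y = _two_stage_solve(rhs, 1, delays, sigma)
        return {"donor": np.zeros_like(delays), "acceptor": y[0]}

    def rhs(t, y):
        df, ds, a = y
        return [
            f * g(t) - (kf + kd) * df,
            (1.0 - f) * g(t) - (ks + kd) * ds,
            kf * df + ks * ds - ka * a,
        ]

    y = _two_stage_solve(rhs, 3, delays, sigma)
    return {"donor": y[0] + y[1], "acceptor": y[2]}


def _two_stage_solve(rhs, n_states: int, delays: np.ndarray, sigma: float) -> np.ndarray:
    """Integrate finely across the narrow excitation pulse, then freely.

    The Gaussian source is orders of magnitude narrower than the delay span,
    so an adaptive solver launched over the full span can step across it;
    stage one caps the step size through the pulse window.
    """
    t_start = min(delays[0], -10.0 * sigma)
    t_split = 10.0 * sigma
    t_end = max(delays[-1], t_split)
    ev1 = delays[delays <= t_split]
    ev2 = delays[delays > t_split]
    sol1 = solve_ivp(
        rhs,
        (t_start, t_split),
        np.zeros(n_states),
        dense_output=True,
        method="LSODA",
        rtol=1e-11,
        atol=1e-14,
        max_step=sigma / 4.0,
    )
    out = np.empty((n_states, delays.size))
    if ev1.size:
        out[:, : ev1.size] = sol1.sol(ev1)
    if ev2.size:
        sol2 = solve_ivp(
            rhs,
            (t_split, t_end),
            sol1.y[:, -1],
            t_eval=ev2,
            method="LSODA",
            rtol=1e-11,
            atol=1e-14,
        )
        out[:, ev1.size :] = sol2.y
    return out


def brute_minima(distance: np.ndarray, free_energy: np.ndarray, min_prominence: float):
    """Exhaustive-scan local minima with prominence filtering.

    A point is a candidate if strictly lower than both neighbors. Its
    prominence (on the inverted profile) is measured against the lowest
    barrier separating it from deeper minima or the profile ends.
    """
    g = -np.asarray(free_energy, dtype=float)
    n = g.size
    out = []
    for i in range(1, n - 1):
        if not (g[i] > g[i - 1] and g[i] > g[i + 1]):
            continue
        # walk left/right to the nearest strictly higher point (or end),
        # tracking the deepest valley crossed on each side
        left_min = np.inf
        j = i - 1
        while j >= 0 and g[j] <= g[i]:
            left_min = min(left_min, g[j])
            j -= 1
        right_min = np.inf
        j = i + 1
        while j < n and g[j] <= g[i]:
            right_min = min(right_min, g[j])
            j += 1
        # prominence is measured from the higher of the two side bases
        prominence = g[i] - max(left_min, right_min)
        if prominence >= min_prominence:
            out.append(float(distance[i]))
    return out


def bound_fraction_root(peptide: float, ligand_total: float, kd: float) -> float:
    """Single-site bound fraction by root finding on the mass balance."""
    if peptide == 0.0:
        return 0.0

    def h(pl):
        return (peptide - pl) * (ligand_total - pl) - kd * pl

    hi = min(peptide, ligand_total)
    return brentq(h, 0.0, hi, xtol=1e-15, rtol=1e-14) / ligand_total


def riemann_overlap(donor, acceptor, n: int = 200_001) -> float:
    """Overlap integral by dense midpoint Riemann summation."""
    lo = max(donor.wavelengths[0], acceptor.wavelengths[0])
    hi = min(donor.wavelengths[-1], acceptor.wavelengths[-1])
    grid = np.linspace(lo, hi, n)
    mid = 0.5 * (grid[1:] + grid[:-1])
    dl = np.diff(grid)
    fd = donor.interp(mid) / donor.area()
    return float(np.sum(fd * acceptor.interp(mid) * mid**4 * dl))


def competitive_dye_signal(
    peptide: np.ndarray, dye_total: float, comp_total: float, kd_dye: float, kd_comp: float
) -> np.ndarray:
    """Mass-action equilibrium for two ligands competing for one site.

    Solves for free sites P by root finding on total-site balance, then
    returns the bound-dye fraction per peptide concentration.
    """
    out = []
    for P_tot in np.atleast_1d(peptide):
        if P_tot == 0.0:
            out.append(0.0)
            continue

        def free_ligand(l_tot, kd, p_free):
            # L_free from L_tot = L_free (1 + P_free/kd)
            return l_tot / (1.0 + p_free / kd)

        def balance(p_free):
            ld = free_ligand(dye_total, kd_dye, p_free)
            lc = free_ligand(comp_total, kd_comp, p_free)
            return p_free * (1.0 + ld / kd_dye + lc / kd_comp) - P_tot

        p_free = brentq(balance, 0.0, P_tot, xtol=1e-14)
        ld = free_ligand(dye_total, kd_dye, p_free)
        out.append((dye_total - ld) / dye_total)
    return np.asarray(out)
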