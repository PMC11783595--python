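"""TCSPC reconvolution analysis.

A time-correlated single-photon-counting histogram is modelled as a sum of
exponentials convolved with a Gaussian instrument response function (IRF).
The convolution is evaluated analytically per component,

    h(t) = (α/2) exp(σ²/(2τ²) − (t−t0)/τ) erfc((σ/τ − (t−t0)/σ)/√2),

numerically stabilized through the scaled complementary error function
(erfcx) where the plain form would overflow (σ ≪ τ, t ≫ t0). Negative
amplitudes encode rise components (sensitized acceptor emission fed by
energy transfer); fitting uses Poisson maximum likelihood via deviance
residuals by default, which is the correct statistic for counting data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc, erfcx

__all__ = [
    "exp_gauss",
    "MultiExpModel",
    "DecayTrace",
    "FitResult",
    "RiseResult",
    "convolve_model",
    "fit_reconvolution",
    "average_lifetime",
    "select_model",
    "extract_fret_time",
]

_SQRT2 = np.sqrt(2.0)


def exp_gauss(t: np.ndarray, tau: float, sigma: float, t0: float = 0.0) -> np.ndarray:
    """Unit-amplitude exponential decay convolved with a normalized Gaussian.

    Returns exp(-(t-t0)/tau)*step(t-t0) ⊗ N(0, sigma²). ``tau=np.inf`` gives
    the IRF-integrated step (cumulative Gaussian). As sigma → 0 the plain
    shifted exponential is recovered.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=float)
    tt = t - t0
    k = 0.0 if np.isinf(tau) else 1.0 / tau
    x = (sigma * k - tt / sigma) / _SQRT2
    out = np.empty_like(tt)
    pos = x >= 0
    # erfcx form: erfc(x) e^y = erfcx(x) e^{y - x^2}, and y - x^2 = -tt^2/(2 sigma^2)
    out[pos] = 0.5 * erfcx(x[pos]) * np.exp(-(tt[pos] ** 2) / (2.0 * sigma**2))
    # direct form is safe for x < 0: exponent sigma^2 k^2/2 - k*tt < 0 there
    out[~pos] = 0.5 * np.exp(0.5 * (sigma * k) ** 2 - k * tt[~pos]) * erfc(x[~pos])
    return out


@dataclass
class MultiExpModel:
    """Sum-of-exponentials decay model.

    Amplitudes are signed: a negative amplitude is a rise component.
    Lifetimes (ns) must be positive and sorted ascending, with the amplitudes
    aligned to them; at least one amplitude must be positive.
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray
    baseline: float = 0.0
    t0_shift: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.lifetimes = np.atleast_1d(np.asarray(self.lifetimes, dtype=float))
        if self.amplitudes.shape != self.lifetimes.shape:
            raise ValueError("amplitudes and lifetimes must have the same length")
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be strictly positive")
        if np.any(np.diff(self.lifetimes) < 0):
            raise ValueError("lifetimes must be sorted ascending")
        # a rise (negative) component needs a positive decay partner; an
        # all-zero amplitude vector (dark sample) is allowed
        if np.any(self.amplitudes != 0) and not np.any(self.amplitudes > 0):
            raise ValueError("at least one amplitude must be positive")

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)


@dataclass
class DecayTrace:
    """A TCSPC histogram together with its instrument response trace."""

    time: np.ndarray  # channel centers, ns
    counts: np.ndarray
    irf_counts: np.ndarray
    channel_width: float  # ns
    window_warning: bool = False  # acquisition window < 5x longest lifetime

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.irf_counts = np.asarray(self.irf_counts, dtype=float)
        if not (self.time.shape == self.counts.shape == self.irf_counts.shape):
            raise ValueError("time, counts and irf_counts must have matching shapes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")

    def irf_moments(self) -> tuple[float, float]:
        """(t0, sigma) of the IRF from thresholded histogram moments.

        Channels below 1% of the IRF peak are zeroed first so that baseline
        counts do not bias the moments.
        """
        w = self.irf_counts.astype(float).copy()
        peak = w.max()
        if peak <= 0:
            raise ValueError("empty IRF trace")
        w[w < 0.01 * peak] = 0.0
        total = w.sum()
        t0 = float((w * self.time).sum() / total)
        var = float((w * (self.time - t0) ** 2).sum() / total)
        return t0, float(np.sqrt(max(var, (self.channel_width / _SQRT2) ** 2 / 6.0)))


@dataclass
class FitResult:
    """Outcome of a reconvolution fit."""

    model: MultiExpModel
    param_errors: dict
    reduced_chi2: float
    n_iter: int
    converged: bool
    residuals: np.ndarray
    statistic: str = "poisson_mle"
    flags: tuple = ()

    @property
    def bic(self) -> float:
        n = self.residuals.size
        p = 2 * self.model.n_components + 2
        return float(np.sum(self.residuals**2) + p * np.log(n))


def convolve_model(model: MultiExpModel, time: np.ndarray, irf_sigma: float) -> np.ndarray:
    """Expected (noise-free) counts for a model on a channel grid."""
    if irf_sigma <= 0:
        raise ValueError("irf_sigma must be positive")
    time = np.asarray(time, dtype=float)
    out = np.full(time.shape, float(model.baseline))
    for alpha, tau in zip(model.amplitudes, model.lifetimes):
        with np.errstate(over="raise"):
            try:
                out += alpha * exp_gauss(time, tau, irf_sigma, t0=model.t0_shift)
            except FloatingPointError as exc:  # pragma: no cover - defensive
                raise OverflowError(
                    f"convolution overflow for component tau={tau} ns"
                ) from exc
    return out


def _deviance_residuals(counts: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
    d = 2.0 * (mu - counts + term)
    return np.sign(counts - mu) * np.sqrt(np.maximum(d, 0.0))


def _ls_residuals(counts: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return (counts - mu) / np.sqrt(np.maximum(counts, 1.0))


def _residual_fn(statistic: str):
    if statistic == "poisson_mle":
        return _deviance_residuals
    if statistic == "weighted_ls":
        return _ls_residuals
    raise ValueError(f"unknown statistic {statistic!r}")


def _stderr_from_jac(jac: np.ndarray) -> np.ndarray:
    """Asymptotic standard errors from the information matrix J^T J."""
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def _nnls_amplitudes(counts, basis, baseline_col):
    """Nonnegative LS amplitudes for fixed lifetimes — cheap fit initializer."""
    from scipy.optimize import nnls

    A = np.column_stack(basis + [baseline_col])
    coef, _ = nnls(A, counts)
    return coef


def fit_reconvolution(
    trace: DecayTrace,
    n_components: int = 1,
    statistic: str = "poisson_mle",
    irf_sigma: float | None = None,
    n_starts: int = 5,
) -> FitResult:
    """Fit a multi-exponential reconvolution model to a decay histogram.

    Lifetime starting values are log-spaced over [channel width, t_max/2]
    (multi-start); amplitudes are initialized by nonnegative least squares at
    fixed lifetimes. The IRF width/position are taken from the trace's IRF
    histogram moments unless ``irf_sigma`` is given; the time-zero shift is
    co-fitted.
    """
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be in [1, 4]")
    n_params = 2 * n_components + 2
    if trace.counts.size < 10 * n_params:
        raise ValueError("trace too short: need >= 10 channels per free parameter")
    resid_fn = _residual_fn(statistic)

    t = trace.time
    y = trace.counts
    t0_irf, sigma_irf = trace.irf_moments()
    if irf_sigma is not None:
        sigma_irf = float(irf_sigma)
    dt = trace.channel_width
    t_max = t[-1]

    pre = t < t0_irf - 5 * sigma_irf
    base0 = float(np.median(y[pre])) if pre.sum() >= 10 else float(np.min(y))

    lo_tau, hi_tau = max(2 * dt, 1e-3), t_max / 2.0
    grid = np.geomspace(lo_tau * 2, hi_tau, n_starts + n_components - 1)
    tau_starts = [grid[j : j + n_components] for j in range(n_starts)]
    # data-driven start: tail log-slope estimate
    tail = slice(int(0.5 * y.size), int(0.9 * y.size))
    ytail = np.maximum(y[tail] - base0, 0.5)
    slope = np.polyfit(t[tail], np.log(ytail), 1)[0]
    if slope < -1e-9:
        tau_est = np.clip(-1.0 / slope, lo_tau, hi_tau)
        tau_starts.insert(0, np.geomspace(tau_est / (4.0**(n_components - 1)), tau_est, n_components))

    peak = float(y.max())

    def pack(amps, taus, base, t0):
        return np.concatenate([amps, taus, [base, t0]])

    def unpack(x):
        return (
            x[:n_components],
            x[n_components : 2 * n_components],
            x[2 * n_components],
            x[2 * n_components + 1],
        )

    def model_of(x):
        amps, taus, base, t0 = unpack(x)
        mu = np.full_like(t, base)
        for a, tau in zip(amps, taus):
            mu += a * exp_gauss(t, tau, sigma_irf, t0=t0)
        return mu

    def residuals(x):
        return resid_fn(y, model_of(x))

    lb = pack(np.zeros(n_components), np.full(n_components, dt / 4.0), 0.0, t0_irf - 2.0)
    ub = pack(
        np.full(n_components, 10 * peak),
        np.full(n_components, 10 * t_max),
        peak,
        t0_irf + 2.0,
    )

    best = None
    for taus0 in tau_starts:
        taus0 = np.clip(np.sort(np.asarray(taus0, dtype=float)), dt / 2.0, 5 * t_max)
        basis = [exp_gauss(t, tau, sigma_irf, t0=t0_irf) for tau in taus0]
        coef = _nnls_amplitudes(y, basis, np.ones_like(t))
        amps0 = np.maximum(coef[:-1], 1e-6 * peak)
        x0 = np.clip(pack(amps0, taus0, max(base0, 1e-6), t0_irf), lb, ub)
        try:
            res = least_squares(
                residuals, x0, bounds=(lb, ub), x_scale="jac", max_nfev=400 * n_params
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        raise RuntimeError("reconvolution fit failed to converge from all starts")

    amps, taus, base, t0 = unpack(best.x)
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]

    stderr_all = _stderr_from_jac(best.jac)
    amp_err = stderr_all[:n_components][order]
    tau_err = stderr_all[n_components : 2 * n_components][order]

    flags = []
    total_amp = np.sum(np.abs(amps))
    keep = np.abs(amps) >= 1e-3 * total_amp if total_amp > 0 else np.ones_like(amps, bool)
    if not keep.all():
        flags.append("pruned_small_components")
        if not keep.any():
            keep[np.argmax(np.abs(amps))] = True
        amps, taus = amps[keep], taus[keep]
        amp_err, tau_err = amp_err[keep], tau_err[keep]
    if np.any(np.isclose(taus, dt / 4.0)) or np.any(np.isclose(taus, 10 * t_max)):
        flags.append("lifetime_at_bound")

    model = MultiExpModel(np.maximum(amps, 1e-300), taus, baseline=base, t0_shift=t0)
    resid = best.fun
    red = float(np.sum(resid**2) / max(resid.size - n_params, 1))
    return FitResult(
        model=model,
        param_errors={
            "amplitudes": amp_err,
            "lifetimes": tau_err,
            "baseline": stderr_all[2 * n_components],
            "t0_shift": stderr_all[2 * n_components + 1],
        },
        reduced_chi2=red,
        n_iter=int(best.nfev),
        converged=bool(best.status > 0),
        residuals=resid,
        statistic=statistic,
        flags=tuple(flags),
    )


def average_lifetime(model: MultiExpModel, weighting: str = "intensity") -> float:
    """Average lifetime over positive-amplitude components.

    'intensity' weighting (default) returns Σ αᵢτᵢ² / Σ αᵢτᵢ; 'amplitude'
    weighting returns Σ αᵢτᵢ / Σ αᵢ. Rise components (negative amplitudes)
    are excluded.
    """
    pos = model.amplitudes > 0
    if not pos.any():
        raise ValueError("no positive-amplitude components to average")
    a, tau = model.amplitudes[pos], model.lifetimes[pos]
    if weighting == "intensity":
        return float(np.sum(a * tau**2) / np.sum(a * tau))
    if weighting == "amplitude":
        return float(np.sum(a * tau) / np.sum(a))
    raise ValueError(f"unknown weighting {weighting!r}")


def select_model(
    trace: DecayTrace,
    max_components: int = 3,
    statistic: str = "poisson_mle",
    irf_sigma: float | None = None,
    bic_margin: float = 10.0,
) -> tuple[int, dict[int, FitResult]]:
    """Choose the component count by a parsimony rule on BIC.

    Fits n = 1..max_components and returns the smallest n whose BIC lies
    within ``bic_margin`` of the global minimum, together with all fits.
    """
    if max_components > 4:
        raise ValueError("max_components must be <= 4")
    fits: dict[int, FitResult] = {}
    for n in range(1, max_components + 1):
        try:
            fits[n] = fit_reconvolution(trace, n, statistic=statistic, irf_sigma=irf_sigma)
        except (ValueError, RuntimeError):
            continue
    if not fits:
        raise RuntimeError("no component count could be fitted")
    bics = {n: f.bic for n, f in fits.items()}
    best_bic = min(bics.values())
    chosen = min(n for n, b in bics.items() if b <= best_bic + bic_margin)
    # a dark sample: the decay components carry a negligible share of the
    # total counts (everything sits in the baseline)
    m = fits[chosen].model
    decay_counts = float(np.sum(m.amplitudes * m.lifetimes) / trace.channel_width)
    if decay_counts < 0.01 * trace.counts.sum():
        fits[chosen].flags = fits[chosen].flags + ("amplitude_near_zero",)
    return chosen, fits


@dataclass
class RiseResult:
    """Acceptor-channel rise analysis: FRET time constant and amplitude ratio."""

    tau_rise: float | None
    tau_rise_err: float | None
    amplitude_ratio: float | None  # alpha_rise / alpha_decay
    resolvable: bool
    fit: FitResult | None = None


def extract_fret_time(
    acceptor_trace: DecayTrace,
    acceptor_lifetime_fixed: float,
    statistic: str = "poisson_mle",
    irf_sigma: float | None = None,
) -> RiseResult:
    """Fit (−α_rise, τ_rise) + (α_decay, τ_fixed) to an acceptor-channel decay.

    The acceptor decay lifetime is fixed (from a direct-excitation control);
    the rise time constant — the FRET transfer time — and the rise:decay
    amplitude ratio are fitted. If the fitted rise amplitude is statistically
    indistinguishable from zero, a 'no resolvable rise' outcome is returned.
    """
    if acceptor_lifetime_fixed <= 0:
        raise ValueError("acceptor lifetime must be positive")
    resid_fn = _residual_fn(statistic)
    t, y = acceptor_trace.time, acceptor_trace.counts
    t0_irf, sigma_irf = acceptor_trace.irf_moments()
    if irf_sigma is not None:
        sigma_irf = float(irf_sigma)
    dt = acceptor_trace.channel_width
    tau_fix = float(acceptor_lifetime_fixed)
    peak = float(y.max())

    # x = [a_dec, rho, tau_rise, baseline, t0]; model = a_dec*(E(tau_fix) - rho*E(tau_rise)) + base
    def model_of(x):
        a, rho, tau_r, base, t0 = x
        return a * (exp_gauss(t, tau_fix, sigma_irf, t0) - rho * exp_gauss(t, tau_r, sigma_irf, t0)) + base

    def residuals(x):
        return resid_fn(y, np.maximum(model_of(x), 0.0))

    tau_lo, tau_hi = max(2 * dt, 1e-3), 0.95 * tau_fix
    lb = np.array([0.0, 0.0, tau_lo, 0.0, t0_irf - 1.0])
    ub = np.array([10 * peak, 1.5, tau_hi, peak, t0_irf + 1.0])
    pre = t < t0_irf - 5 * sigma_irf
    base0 = float(np.median(y[pre])) if pre.sum() >= 10 else float(np.min(y))

    best = None
    for tau_r0 in np.clip([0.2, 0.5, 1.0, 2.0], tau_lo * 1.01, tau_hi * 0.99):
        x0 = np.clip(np.array([peak, 0.1, tau_r0, max(base0, 1e-6), t0_irf]), lb, ub)
        try:
            res = least_squares(residuals, x0, bounds=(lb, ub), x_scale="jac", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("rise fit failed to converge from all starts")

    a, rho, tau_r, base, t0 = best.x
    stderr = _stderr_from_jac(best.jac)
    rho_err, tau_err = stderr[1], stderr[2]
    resid = best.fun
    red = float(np.sum(resid**2) / max(resid.size - 5, 1))
    model = MultiExpModel(
        np.array([-rho * a, a]), np.array([tau_r, tau_fix]), baseline=base, t0_shift=t0
    ) if rho > 0 else MultiExpModel([a], [tau_fix], baseline=base, t0_shift=t0)
    fit = FitResult(
        model=model,
        param_errors={"amplitude_ratio": rho_err, "tau_rise": tau_err},
        reduced_chi2=red,
        n_iter=int(best.nfev),
        converged=bool(best.status > 0),
        residuals=resid,
        statistic=statistic,
    )
    resolvable = rho >= 0.005 and (not np.isfinite(rho_err) or rho >= 2.0 * rho_err)
    if not resolvable:
        return RiseResult(None, None, float(rho), False, fit)
    return RiseResult(float(tau_r), float(tau_err), float(rho), True, fit)
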