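"""Passive nanorheometry from single-particle trajectories.

Time-averaged MSD with an overlap-aware variance estimator, diffusion
coefficients and hydrodynamic radii through the Stokes-Einstein relation,
complex viscoelastic moduli through Mason's local power-law form of the
generalized Stokes-Einstein relation, and decomposition of position power
spectra into thermal and active force contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import gammaln

from . import constants as c
from .synthetic import MediumModel, glycerol_viscosity
from .trajectory import Trajectory

TRANSVERSE = ("x", "y")

# ---------------------------------------------------------------------------
# MSD


@dataclass
class MsdCurve:
    """Time-averaged MSD on a lag grid, in um^2.

    `variance` (um^4) holds the overlap-aware estimate of the stochastic
    variance of the time average where computed (NaN elsewhere);
    `below_noise` flags lags at or below the instrument noise floor.
    """

    lags: np.ndarray  # s
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # K = N - tau per lag
    axes_used: tuple[str, ...]
    variance: np.ndarray | None = None  # um^4
    noise_floor: float = 1e-4  # um^2
    below_noise: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")
        if self.variance is None:
            self.variance = np.full_like(self.msd, np.nan)
        self.below_noise = self.msd <= self.noise_floor

    def combined_error(self) -> np.ndarray:
        """Per-lag MSD error in um^2.

        The statistical error is sqrt(variance); whenever that error or the
        MSD itself falls below the noise floor, the noise floor is reported
        instead (instrument-limited regime).
        """
        stat = np.sqrt(np.where(np.isfinite(self.variance), self.variance, np.inf))
        out = np.where((stat < self.noise_floor) | (self.msd < self.noise_floor),
                       self.noise_floor, stat)
        return out


def _msd_1d_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD of one coordinate for lags 1..max_lag, O(N log N).

    Uses MSD(tau) = (S1(tau) - 2*S2(tau)) / (N - tau) with S2 the
    autocorrelation computed by FFT and S1 by a recursive sum.
    """
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    s2 = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    x2 = x * x
    # S1(tau) = sum_{i} x_i^2 + x_{i+tau}^2 over valid pairs
    css = np.concatenate([[0.0], np.cumsum(x2)])
    total = css[-1]
    taus = np.arange(1, max_lag + 1)
    s1 = 2.0 * total - css[taus] - (total - css[n - taus])
    k = n - taus
    return (s1 - 2.0 * s2[taus]) / k


def compute_msd(
    traj: Trajectory,
    axes: tuple[str, ...] = TRANSVERSE,
    max_lag: int | None = None,
) -> MsdCurve:
    """Time-averaged MSD over the selected axes (axis contributions summed).

    MSD(tau) = (1/K) * sum_i |r(i+tau) - r(i)|^2 with K = N - tau,
    computed for lags up to N/4 by default (longer lags average too few
    pairs for reliable statistics).
    """
    pos = traj.axis_columns(axes)
    n = pos.shape[0]
    if max_lag is None:
        max_lag = n // 4
    max_lag = int(min(max(max_lag, 1), n - 1))
    msd_nm2 = np.zeros(max_lag)
    for col in pos.T:
        msd_nm2 += _msd_1d_fft(np.ascontiguousarray(col), max_lag)
    taus = np.arange(1, max_lag + 1)
    return MsdCurve(
        lags=taus * traj.sampling_period,
        msd=msd_nm2 * c.NM2_TO_UM2,
        n_pairs=n - taus,
        axes_used=tuple(axes),
        noise_floor=traj.noise_floor,
    )


def msd_variance(
    traj: Trajectory, tau_steps: int, axes: tuple[str, ...] = TRANSVERSE
) -> tuple[float, bool]:
    """Variance of the time-averaged MSD at a lag of `tau_steps` samples.

    Overlapping displacement pairs xi_i = x(i+tau) - x(i) and xi_j are
    correlated for |i - j| < tau because they share trajectory data.  For
    Gaussian increments Cov(xi_i^2, xi_j^2) = 2*Cov(xi_i, xi_j)^2, so the
    variance of the time average is assembled from the empirical
    autocovariance of the displacement sequence:

        Var[MSD] = (2/K^2) * sum_{|d|<tau} (K - |d|) * c_hat(d)^2

    summed per axis and added across axes (spatial directions are
    uncorrelated).  Valid in the regime tau << K and K >> 1; the returned
    flag is False when tau > K/10 or K < 100.  Units: um^4.
    """
    pos = traj.axis_columns(axes)
    n = pos.shape[0]
    k = n - tau_steps
    if tau_steps < 1 or k < 2:
        raise ValueError("lag out of range")
    in_regime = (tau_steps <= k / 10) and (k >= 100)
    if not in_regime:
        warnings.warn(
            f"msd variance outside its validity regime (tau={tau_steps}, K={k})",
            stacklevel=2,
        )
    var_nm4 = 0.0
    for col in pos.T:
        xi = col[tau_steps:] - col[:-tau_steps]
        xi = xi - xi.mean()
        # autocovariance of the displacement sequence up to lag tau-1
        nfft = 1 << int(np.ceil(np.log2(2 * k)))
        fx = np.fft.rfft(xi, nfft)
        acov = np.fft.irfft(fx * np.conj(fx), nfft)[:tau_steps] / k
        d = np.arange(tau_steps)
        var_nm4 += (2.0 / k**2) * np.sum(
            np.concatenate([[k], 2.0 * (k - d[1:])]) * acov**2
        )
    return var_nm4 * c.NM2_TO_UM2**2, in_regime


def attach_msd_variance(
    traj: Trajectory, curve: MsdCurve, lags_steps: np.ndarray | None = None
) -> MsdCurve:
    """Fill `curve.variance` at the requested integer lags (default: all
    lags in the regime tau <= K/10)."""
    steps = np.round(curve.lags / traj.sampling_period).astype(int)
    if lags_steps is None:
        lags_steps = steps[steps <= (len(traj) - steps) / 10]
    variance = np.array(curve.variance, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in np.asarray(lags_steps, dtype=int):
            where = np.nonzero(steps == s)[0]
            if where.size:
                variance[where[0]] = msd_variance(traj, int(s), curve.axes_used)[0]
    curve.variance = variance
    return curve


def ensemble_msd(
    trajs: list[Trajectory],
    axes: tuple[str, ...] = TRANSVERSE,
    max_lag: int | None = None,
) -> MsdCurve:
    """Pair-count-weighted average of the per-trajectory time-averaged MSDs.

    The weighting makes the result identical to pooling all displacement
    pairs of the individual trajectories (junction-crossing pairs of a
    naive concatenation never enter).
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    dt = trajs[0].sampling_period
    if any(not np.isclose(t.sampling_period, dt) for t in trajs):
        raise ValueError("trajectories must share a sampling period")
    curves = [compute_msd(t, axes=axes, max_lag=max_lag) for t in trajs]
    n_lags = min(c_.msd.size for c_ in curves)
    weights = np.stack([c_.n_pairs[:n_lags] for c_ in curves])
    values = np.stack([c_.msd[:n_lags] for c_ in curves])
    msd = np.sum(weights * values, axis=0) / np.sum(weights, axis=0)
    return MsdCurve(
        lags=curves[0].lags[:n_lags],
        msd=msd,
        n_pairs=np.sum(weights, axis=0),
        axes_used=tuple(axes),
        noise_floor=trajs[0].noise_floor,
    )


# ---------------------------------------------------------------------------
# diffusion and Stokes-Einstein


@dataclass
class DiffusionEstimate:
    """Diffusion coefficient in nm^2/s with its confidence scale."""

    D: float
    method: str
    lag_used: float  # s
    ci: float  # one-sigma, nm^2/s
    unreliable: bool = False  # MSD at or below noise floor


def estimate_diffusion(
    msd: MsdCurve, method: str = "msd_at_lag", lag: float = 1.0
) -> DiffusionEstimate:
    """Diffusion coefficient from an MSD curve.

    ``msd_at_lag``: D = MSD(lag) / (2*d*lag) at the grid lag nearest the
    requested one (d = number of axes).  ``linear_fit``: variance-weighted
    least squares of MSD = 2*d*D*tau through the origin over lags <= lag.
    """
    d_axes = len(msd.axes_used)
    idx = int(np.argmin(np.abs(msd.lags - lag)))
    lag_used = float(msd.lags[idx])
    if not np.isclose(lag_used, lag, rtol=1e-6):
        warnings.warn(f"using nearest grid lag {lag_used:.4g} s for requested {lag:.4g} s",
                      stacklevel=2)
    unreliable = bool(msd.below_noise[idx])
    if method == "msd_at_lag":
        denom = 2.0 * d_axes * lag_used
        d_val = msd.msd[idx] * c.UM2_TO_NM2 / denom
        err = msd.combined_error()[idx] * c.UM2_TO_NM2 / denom
        return DiffusionEstimate(d_val, method, lag_used, err, unreliable)
    if method == "linear_fit":
        sel = msd.lags <= lag_used * (1 + 1e-9)
        tau = msd.lags[sel]
        y = msd.msd[sel] * c.UM2_TO_NM2
        err = msd.combined_error()[sel] * c.UM2_TO_NM2
        with np.errstate(divide="ignore"):
            w = 1.0 / err**2
        if not np.any(w > 0):  # no variance information: unweighted fit
            w = np.ones_like(tau)
        denom = np.sum(w * tau**2)
        slope = np.sum(w * tau * y) / denom
        slope_se = 1.0 / np.sqrt(denom)
        return DiffusionEstimate(
            slope / (2 * d_axes), method, lag_used, slope_se / (2 * d_axes),
            bool(msd.below_noise[sel].any()),
        )
    raise ValueError(f"unknown method {method!r}")


def stokes_einstein_radius(
    D_series: dict[float, "DiffusionEstimate | float"],
    medium: MediumModel,
) -> tuple[float, float]:
    """Hydrodynamic radius (nm) from D(T) via the Stokes-Einstein relation.

    Fits D(T) = kB*T_abs / (6*pi*eta(T)*r) with r the single free
    parameter.  The model is linear in 1/r, so the least-squares solution
    is closed-form and r is positive whenever the diffusion estimates are.
    Returns (radius, standard error) in nm.
    """
    if not D_series:
        raise ValueError("need at least one temperature point")
    temps = np.array(sorted(D_series))
    d_vals, weights = [], []
    for t in temps:
        entry = D_series[t]
        if isinstance(entry, DiffusionEstimate):
            d_vals.append(entry.D)
            weights.append(1.0 / entry.ci**2 if entry.ci > 0 else 1.0)
        else:
            d_vals.append(float(entry))
            weights.append(1.0)
    d_vals = np.asarray(d_vals)
    w = np.asarray(weights)
    eta = np.asarray([glycerol_viscosity(t, medium) for t in temps])
    t_abs = np.asarray([c.celsius_to_kelvin(t) for t in temps])
    # a(T) = kB*T/(6*pi*eta) in nm^3/s so that D = a/r; model linear in 1/r
    a = c.BOLTZMANN * t_abs / (6.0 * np.pi * eta) * 1e27
    inv_r = np.sum(w * a * d_vals) / np.sum(w * a**2)
    if inv_r <= 0:
        raise ValueError("diffusion estimates imply a non-positive radius")
    r = 1.0 / inv_r
    if temps.size > 1:
        resid = d_vals - a * inv_r
        sigma2 = np.sum(w * resid**2) / (temps.size - 1)
        var_inv_r = sigma2 / np.sum(w * a**2)
    else:
        # direct inversion: propagate the supplied D uncertainty if any
        var_inv_r = 1.0 / (w[0] * a[0] ** 2)
    r_se = r**2 * np.sqrt(var_inv_r)
    return float(r), float(r_se)


# ---------------------------------------------------------------------------
# Mason GSER moduli


@dataclass
class ComplexModulus:
    """Frequency-dependent viscoelastic moduli from the GSER."""

    f: np.ndarray  # Hz
    G_prime: np.ndarray  # Pa, elastic
    G_double_prime: np.ndarray  # Pa, viscous
    G_abs: np.ndarray  # Pa
    loss_tangent: np.ndarray  # rad, delta = pi*alpha/2
    alpha_local: np.ndarray  # log-log MSD gradient at tau = 1/omega
    G_abs_err: np.ndarray | None = None  # Pa, propagated from MSD error


def _local_loglog_slope(log_tau: np.ndarray, log_msd: np.ndarray, half_window: int = 3) -> np.ndarray:
    """Smoothed d(ln MSD)/d(ln tau): quadratic fit over +-half_window points."""
    n = log_tau.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        if hi - lo < 3:
            lo, hi = max(0, hi - 3), min(n, lo + 3)
        coef = np.polyfit(log_tau[lo:hi], log_msd[lo:hi], 2)
        out[i] = 2 * coef[0] * log_tau[i] + coef[1]
    return out


def mason_modulus(
    msd: MsdCurve,
    T: float,
    radius: float,
    n_per_decade: int = 16,
) -> ComplexModulus:
    """Complex modulus G*(f) from the MSD by Mason's power-law GSER.

    At each retained lag tau the modulus magnitude is

        |G*| = 2*kB*T / (3*pi*r * MSD_2D(tau) * Gamma(1 + alpha(tau)))

    for the transverse (2-axis) MSD, with alpha the smoothed local
    log-log slope of the MSD, evaluated at angular frequency
    omega = 1/tau (reported as f = omega/2pi).  The loss tangent is
    delta = pi*alpha/2 and G' = |G*| cos(delta), G'' = |G*| sin(delta);
    a purely viscous medium with MSD = 4*D*tau returns G'' = 2*pi*f*eta
    exactly.  T in kelvin, radius in nm.  Lags at the noise floor are
    excluded; alpha is clipped to [0, 2] with a warning.
    """
    usable = (~msd.below_noise) & (msd.msd > 0)
    if usable.sum() < 4:
        raise ValueError("not enough MSD points above the noise floor")
    lags = msd.lags[usable]
    vals = msd.msd[usable]
    var = np.asarray(msd.variance)[usable]

    # log-spaced subgrid so the local power-law fit is evenly weighted in ln(tau)
    n_decades = np.log10(lags[-1] / lags[0])
    n_pts = max(int(np.ceil(n_decades * n_per_decade)) + 1, 4)
    target = np.geomspace(lags[0], lags[-1], n_pts)
    idx = np.unique(np.searchsorted(lags, target).clip(0, lags.size - 1))
    lags, vals, var = lags[idx], vals[idx], var[idx]

    log_tau = np.log(lags)
    alpha = _local_loglog_slope(log_tau, np.log(vals))
    if np.any((alpha < 0) | (alpha > 2)):
        warnings.warn("local MSD exponent clipped to [0, 2]", stacklevel=2)
        alpha = np.clip(alpha, 0.0, 2.0)

    r_m = radius * c.NM_TO_M
    msd_m2 = vals * c.UM2_TO_M2
    gamma_factor = np.exp(gammaln(1.0 + alpha))
    g_abs = 2.0 * c.BOLTZMANN * T / (3.0 * np.pi * r_m * msd_m2 * gamma_factor)
    delta = np.pi * alpha / 2.0
    omega = 1.0 / lags
    err = None
    if np.any(np.isfinite(var)):
        with np.errstate(invalid="ignore"):
            err = g_abs * np.sqrt(var) / vals  # relative MSD error, alpha error neglected
    order = np.argsort(omega)
    return ComplexModulus(
        f=(omega / (2 * np.pi))[order],
        G_prime=(g_abs * np.cos(delta))[order],
        G_double_prime=(g_abs * np.sin(delta))[order],
        G_abs=g_abs[order],
        loss_tangent=delta[order],
        alpha_local=alpha[order],
        G_abs_err=err[order] if err is not None else None,
    )


# ---------------------------------------------------------------------------
# PSD and force decomposition


@dataclass
class PsdTrace:
    """One-sided position power spectral density, um^2/Hz."""

    f: np.ndarray  # Hz
    psd_per_axis: dict[str, np.ndarray]
    psd_total: np.ndarray  # sum over the transverse axes
    window: float  # s, Welch segment length
    readout_frequency: float = 40.0  # Hz

    def at_frequency(self, f_hz: float | None = None) -> float:
        """Total PSD at the bin nearest the readout frequency."""
        f_hz = self.readout_frequency if f_hz is None else f_hz
        return float(self.psd_total[np.argmin(np.abs(self.f - f_hz))])


def welch_psd(
    traj: Trajectory,
    window: float = 28.8,
    axes: tuple[str, ...] = TRANSVERSE,
    readout_frequency: float = 40.0,
) -> PsdTrace:
    """Welch power spectral density of the position, averaged over
    `window`-second segments; the total is the sum over transverse axes."""
    nperseg = int(round(window / traj.sampling_period))
    if nperseg > len(traj):
        raise ValueError(
            f"window of {window} s exceeds trajectory duration {traj.duration:.3g} s"
        )
    fs = 1.0 / traj.sampling_period
    per_axis: dict[str, np.ndarray] = {}
    for ax in axes:
        col = traj.axis_columns((ax,))[:, 0]
        f, pxx = signal.welch(col, fs=fs, nperseg=nperseg, detrend="constant")
        per_axis[ax] = pxx * c.NM2_TO_UM2
    total = np.sum(list(per_axis.values()), axis=0)
    return PsdTrace(f=f, psd_per_axis=per_axis, psd_total=total,
                    window=window, readout_frequency=readout_frequency)


@dataclass
class ForceDecomposition:
    """Thermal versus active contributions to the position PSD."""

    f: np.ndarray  # Hz
    spring_constant: np.ndarray  # complex, N/m
    thermal_psd_bound: np.ndarray  # um^2/Hz, position PSD a thermal bath explains
    external_force_psd: np.ndarray  # N^2/Hz
    clipped: np.ndarray  # bool, where subtraction went negative
    temperature: float  # K
    radius: float  # nm


def decompose_forces(
    psd: PsdTrace,
    modulus: ComplexModulus,
    T: float,
    radius: float,
    f_range: tuple[float, float] | None = None,
) -> ForceDecomposition:
    """Split the measured position PSD into thermal and active force parts.

    The medium acts as a complex spring K(omega) = 6*pi*r*G*(omega)
    (Hooke's law).  The fluctuation-dissipation theorem fixes the position
    PSD a thermal bath can sustain, per axis S_th = 4*kB*T*K''/(omega*|K|^2)
    (one-sided, in f), doubled for the two transverse axes.  Any excess is
    attributed to active forces:

        <F_ext^2>(f) = |K|^2 * (S_meas - S_th),  clipped at zero.

    |K| and the loss angle are interpolated (log-log) from the modulus
    onto the PSD frequency grid, extrapolating the local power law where
    the grids do not overlap.
    """
    sel = psd.f > 0
    if f_range is not None:
        sel &= (psd.f >= f_range[0]) & (psd.f <= f_range[1])
    f = psd.f[sel]
    if f.size == 0:
        raise ValueError("no positive frequencies selected")
    ok = modulus.G_abs > 0
    log_f_mod = np.log(modulus.f[ok])
    g_abs = np.exp(np.interp(np.log(f), log_f_mod, np.log(modulus.G_abs[ok])))
    delta = np.interp(np.log(f), log_f_mod, modulus.loss_tangent[ok])

    r_m = radius * c.NM_TO_M
    k_abs = 6.0 * np.pi * r_m * g_abs  # N/m
    k_complex = k_abs * np.exp(1j * delta)
    omega = 2.0 * np.pi * f
    n_axes = len(psd.psd_per_axis)
    s_th_m2 = n_axes * 4.0 * c.BOLTZMANN * T * k_complex.imag / (omega * k_abs**2)
    s_meas_m2 = psd.psd_total[sel] * c.UM2_TO_M2
    f_ext = k_abs**2 * (s_meas_m2 - s_th_m2)
    clipped = f_ext < 0
    return ForceDecomposition(
        f=f,
        spring_constant=k_complex,
        thermal_psd_bound=s_th_m2 / c.UM2_TO_M2,
        external_force_psd=np.where(clipped, 0.0, f_ext),
        clipped=clipped,
        temperature=T,
        radius=radius,
    )
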