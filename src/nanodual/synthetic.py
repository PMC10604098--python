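"""Synthetic inputs for the dual-modality pipeline.

Everything the analysis consumes is generated here: 3D particle
trajectories at the 9.6 ms orbital-tracking period (Brownian, fractional
Brownian, directed), photon-count ODMR spectrum streams with the
160/200 ms duty cycle, RTD resistance traces, and a simulator of the
double-plane orbital tracking feedback loop.  Every stochastic operation
takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from . import constants as c
from ._fgn import sample_fgn
from .trajectory import (
    DEFAULT_LOCALIZATION_SIGMA,
    DEFAULT_NOISE_FLOOR,
    DEFAULT_SAMPLING_PERIOD,
    Trajectory,
)

TemperatureProfile = Callable[[np.ndarray], np.ndarray] | float

# ---------------------------------------------------------------------------
# medium


@dataclass
class MediumModel:
    """Viscous medium with linear temperature-dependent viscosity.

    eta(T) = eta0 - mu_abs * (T - T0_visc); viscosity decreases with
    temperature (mu_abs is the magnitude of the slope).  Defaults describe
    glycerol near physiological temperatures and a 25 nm probe.
    """

    eta0: float = 0.301  # Pa s at T0_visc
    mu_abs: float = 0.0208  # Pa s / degC, magnitude of d(eta)/dT
    T0_visc: float = 35.0  # degC
    particle_radius: float = 25.0  # nm
    temperature: float = 35.0  # degC

    TEMPERATURE_RANGE = (21.0, 40.0)

    def __post_init__(self) -> None:
        if self.particle_radius <= 0:
            raise ValueError("particle_radius must be positive")
        lo, hi = self.TEMPERATURE_RANGE
        for t_edge in (lo, hi):
            if self.eta0 - self.mu_abs * (t_edge - self.T0_visc) <= 0:
                raise ValueError("eta(T) must stay positive over 21-40 degC")


def glycerol_viscosity(T: float | np.ndarray, medium: MediumModel | None = None) -> float | np.ndarray:
    """Viscosity in Pa s at temperature T (degC); linear, decreasing in T."""
    medium = medium or MediumModel()
    T = np.asarray(T, dtype=float)
    lo, hi = medium.TEMPERATURE_RANGE
    if np.any(T < lo) or np.any(T > hi):
        warnings.warn(
            f"temperature outside supported range {lo}-{hi} degC; extrapolating",
            stacklevel=2,
        )
    eta = medium.eta0 - medium.mu_abs * (T - medium.T0_visc)
    return float(eta) if eta.ndim == 0 else eta


def stokes_einstein_diffusion(T_celsius: float, medium: MediumModel) -> float:
    """Diffusion coefficient in nm^2/s from the Stokes-Einstein relation."""
    eta = glycerol_viscosity(T_celsius, medium)
    r_m = medium.particle_radius * c.NM_TO_M
    d_m2 = c.BOLTZMANN * c.celsius_to_kelvin(T_celsius) / (6.0 * np.pi * eta * r_m)
    return d_m2 * 1e18


# ---------------------------------------------------------------------------
# trajectories


def _finalize_trajectory(
    positions: np.ndarray,
    dt: float,
    localization_sigma: float,
    rng: np.random.Generator,
    meta: dict[str, Any],
) -> Trajectory:
    if localization_sigma < 0:
        raise ValueError("localization_sigma must be >= 0")
    if localization_sigma > 0:
        positions = positions + rng.normal(scale=localization_sigma, size=positions.shape)
    n = positions.shape[0]
    return Trajectory(
        times=np.arange(n) * dt,
        positions=positions,
        sampling_period=dt,
        localization_sigma=localization_sigma,
        noise_floor=DEFAULT_NOISE_FLOOR,
        meta=meta,
    )


def _check_steps(n_steps: int, dt: float) -> None:
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if dt <= 0:
        raise ValueError(f"sampling period dt must be positive, got {dt}")


def simulate_brownian(
    D: float,
    n_steps: int,
    dt: float = DEFAULT_SAMPLING_PERIOD,
    seed: int = 0,
    localization_sigma: float = DEFAULT_LOCALIZATION_SIGMA,
) -> Trajectory:
    """Free Brownian motion: per-axis increments N(0, 2*D*dt).

    D in nm^2/s.  The per-axis MSD is 2*D*tau, the transverse (x,y) MSD
    4*D*tau.  Localization noise is added per sample on all axes.
    """
    if D < 0:
        raise ValueError(f"diffusion coefficient D must be >= 0, got {D}")
    _check_steps(n_steps, dt)
    rng = np.random.default_rng(seed)
    increments = rng.normal(scale=np.sqrt(2.0 * D * dt), size=(n_steps - 1, 3))
    positions = np.vstack([np.zeros(3), np.cumsum(increments, axis=0)])
    meta = {"generator": "brownian", "D_nm2_s": D, "dt_s": dt, "seed": seed}
    return _finalize_trajectory(positions, dt, localization_sigma, rng, meta)


def simulate_fbm(
    alpha: float,
    scale: float,
    n_steps: int,
    dt: float = DEFAULT_SAMPLING_PERIOD,
    seed: int = 0,
    localization_sigma: float = 0.0,
) -> Trajectory:
    """Fractional Brownian motion with anomalous exponent alpha in (0, 2).

    The per-axis ensemble MSD is 2*scale*tau^alpha (scale in nm^2/s^alpha),
    so alpha=1, scale=D reproduces the Brownian statistics.  Increments are
    fractional Gaussian noise with Hurst index alpha/2.
    """
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must be in (0, 2), got {alpha}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    _check_steps(n_steps, dt)
    rng = np.random.default_rng(seed)
    sigma_step = np.sqrt(2.0 * scale * dt**alpha)
    fgn = sample_fgn(n_steps - 1, hurst=alpha / 2.0, rng=rng, size=3) * sigma_step
    positions = np.vstack([np.zeros(3), np.cumsum(fgn.T, axis=0)])
    meta = {
        "generator": "fbm",
        "alpha": alpha,
        "scale_nm2_s_alpha": scale,
        "dt_s": dt,
        "seed": seed,
    }
    return _finalize_trajectory(positions, dt, localization_sigma, rng, meta)


def simulate_directed(
    v: float,
    D: float,
    direction: np.ndarray,
    n_steps: int,
    dt: float = DEFAULT_SAMPLING_PERIOD,
    seed: int = 0,
    localization_sigma: float = DEFAULT_LOCALIZATION_SIGMA,
) -> Trajectory:
    """Ballistic drift v*t along `direction` plus Brownian motion.

    Exact per-axis-summed MSD (transverse projection of the drift included)
    is 4*D*tau + (v*tau)^2 in 2D when the drift lies in-plane.  With v=0 the
    output is bit-identical to `simulate_brownian` at the same seed.
    """
    if v < 0:
        raise ValueError("speed v must be >= 0")
    if D < 0:
        raise ValueError(f"diffusion coefficient D must be >= 0, got {D}")
    _check_steps(n_steps, dt)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    direction = direction / norm

    rng = np.random.default_rng(seed)
    increments = rng.normal(scale=np.sqrt(2.0 * D * dt), size=(n_steps - 1, 3))
    positions = np.vstack([np.zeros(3), np.cumsum(increments, axis=0)])
    drift = v * (np.arange(n_steps) * dt)[:, None] * direction[None, :]
    positions = positions + drift
    meta = {
        "generator": "directed",
        "v_nm_s": v,
        "D_nm2_s": D,
        "direction": direction.tolist(),
        "dt_s": dt,
        "seed": seed,
    }
    return _finalize_trajectory(positions, dt, localization_sigma, rng, meta)


def simulate_brownian_varying(
    D_of_t: Callable[[np.ndarray], np.ndarray],
    n_steps: int,
    dt: float = DEFAULT_SAMPLING_PERIOD,
    seed: int = 0,
    localization_sigma: float = DEFAULT_LOCALIZATION_SIGMA,
) -> Trajectory:
    """Brownian motion whose diffusion coefficient follows a time profile.

    Used by the pipeline presets where the medium temperature (hence D via
    Stokes-Einstein) is stepped during a run.
    """
    _check_steps(n_steps, dt)
    t_mid = (np.arange(n_steps - 1) + 0.5) * dt
    d_vals = np.asarray(D_of_t(t_mid), dtype=float)
    if np.any(d_vals < 0):
        raise ValueError("D(t) must be >= 0")
    rng = np.random.default_rng(seed)
    increments = rng.normal(size=(n_steps - 1, 3)) * np.sqrt(2.0 * d_vals * dt)[:, None]
    positions = np.vstack([np.zeros(3), np.cumsum(increments, axis=0)])
    meta = {"generator": "brownian_varying", "dt_s": dt, "seed": seed}
    return _finalize_trajectory(positions, dt, localization_sigma, rng, meta)


# ---------------------------------------------------------------------------
# ODMR spectrum streams


@dataclass
class SpectrumModel:
    """Continuous-wave ODMR lineshape of a nanodiamond NV ensemble.

    The photoluminescence dips on resonance; the ensemble spectrum is
    modeled as one broad Lorentzian dip or two dips split symmetrically
    about the center frequency.  `contrast` is the fractional PL drop at
    the deepest point; `baseline_rate` the off-resonance photon rate
    (both detectors summed).
    """

    center_frequency: float = 2870.0  # MHz
    contrast: float = 0.10  # fractional dip depth
    linewidth: float = 8.0  # MHz FWHM per dip
    n_dips: int = 2
    splitting: float = 6.0  # MHz between the two dips
    baseline_rate: float = 1e6  # counts/s, both APDs summed

    def __post_init__(self) -> None:
        if not 0.0 < self.contrast < 1.0:
            raise ValueError("contrast must be in (0, 1)")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.n_dips not in (1, 2):
            raise ValueError("n_dips must be 1 or 2")

    def _raw_dip(self, f: np.ndarray, center: float) -> np.ndarray:
        hw = self.linewidth / 2.0
        lor = lambda f0: hw**2 / ((f - f0) ** 2 + hw**2)  # noqa: E731
        if self.n_dips == 1:
            return lor(center)
        return lor(center - self.splitting / 2.0) + lor(center + self.splitting / 2.0)

    def profile(self, f: np.ndarray, center: float | None = None) -> np.ndarray:
        """Relative PL level in [1-contrast, 1] at frequencies f (MHz)."""
        center = self.center_frequency if center is None else center
        f = np.asarray(f, dtype=float)
        raw = self._raw_dip(f, center)
        # normalize so the deepest point of the lineshape sits at 1-contrast
        fine = np.linspace(center - self.linewidth - self.splitting,
                           center + self.linewidth + self.splitting, 2001)
        peak = self._raw_dip(fine, center).max()
        return 1.0 - self.contrast * raw / peak


@dataclass
class OdmrTimeSeries:
    """Stream of 200-point ODMR spectra with duty-cycle timing metadata.

    `counts` holds photon counts per frequency point either summed per
    160 ms window (shape (n_windows, n_points), the memory-friendly default;
    a sum of Poisson scans is Poisson) or per 2 ms scan
    (shape (n_windows, scans_per_window, n_points)).  No counts are
    collected during the 40 ms off period of each 200 ms duty cycle.
    """

    frequency_grid: np.ndarray  # MHz, strictly increasing
    counts: np.ndarray  # int
    scans_per_window: int = 80
    scan_time: float = 2e-3  # s
    window_time: float = 0.16  # s
    duty_cycle_period: float = 0.2  # s
    gate_time: float = 10e-6  # s per frequency point
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency_grid = np.asarray(self.frequency_grid, dtype=float)
        self.counts = np.asarray(self.counts)
        if not np.all(np.diff(self.frequency_grid) > 0):
            raise ValueError("frequency_grid must be strictly increasing")
        if self.counts.ndim not in (2, 3):
            raise ValueError("counts must be (n_windows, n_points) or (n_windows, n_scans, n_points)")
        if self.counts.shape[-1] != self.frequency_grid.size:
            raise ValueError("counts last axis must match frequency grid")
        if self.per_scan and self.counts.shape[1] != self.scans_per_window:
            raise ValueError("per-scan counts second axis must be scans_per_window")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.isclose(self.scans_per_window * self.scan_time, self.window_time):
            raise ValueError("scans_per_window * scan_time must equal window_time")
        if self.window_time > self.duty_cycle_period:
            raise ValueError("window_time cannot exceed duty_cycle_period")

    @property
    def per_scan(self) -> bool:
        return self.counts.ndim == 3

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def window_start_times(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.duty_cycle_period

    def window_counts(self) -> np.ndarray:
        """Counts summed over scans, shape (n_windows, n_points)."""
        return self.counts.sum(axis=1) if self.per_scan else self.counts

    def mean_spectrum(self, window_slice: slice = slice(None)) -> np.ndarray:
        """Mean counts per gate over the selected windows."""
        w = self.window_counts()[window_slice]
        if w.size == 0:
            raise ValueError("empty window selection")
        return w.mean(axis=0) / self.scans_per_window


def _as_profile(profile: TemperatureProfile) -> Callable[[np.ndarray], np.ndarray]:
    if callable(profile):
        return lambda t: np.asarray(profile(t), dtype=float)
    value = float(profile)
    return lambda t: np.full_like(np.asarray(t, dtype=float), value)


def generate_odmr_series(
    temperature_profile: TemperatureProfile,
    model: SpectrumModel | None = None,
    kappa: float = -60.0,
    duration: float = 10.0,
    seed: int = 0,
    reference_temperature: float | None = None,
    span: float = 30.0,
    n_points: int = 200,
    per_scan: bool = False,
    noiseless: bool = False,
) -> OdmrTimeSeries:
    """Simulate an ODMR photon-count stream whose dip tracks temperature.

    The dip center is center_frequency + kappa*(T(t) - T_ref)/1000 with
    kappa in kHz/degC (default -60: the resonance moves down as the sample
    heats).  Timing honors the 200-point / 2 ms scan / 80-scan window /
    200 ms duty cycle; per-gate counts are Poisson with mean
    baseline_rate * gate_time * dip_profile.  `noiseless` returns expected
    counts (float) instead of Poisson draws.
    """
    model = model or SpectrumModel()
    timing = OdmrTimeSeries(
        frequency_grid=np.linspace(model.center_frequency - span / 2,
                                   model.center_frequency + span / 2, n_points),
        counts=np.zeros((1, n_points), dtype=np.int64),
    )
    if duration < timing.duty_cycle_period:
        raise ValueError("duration must cover at least one duty cycle")
    n_windows = int(duration / timing.duty_cycle_period)
    grid = timing.frequency_grid
    profile_fn = _as_profile(temperature_profile)
    t_mid = np.arange(n_windows) * timing.duty_cycle_period + timing.window_time / 2.0
    temps = profile_fn(t_mid)
    t_ref = float(profile_fn(np.zeros(1))[0]) if reference_temperature is None else reference_temperature
    centers = model.center_frequency + kappa * (temps - t_ref) * c.KHZ_TO_MHZ

    mean_per_gate = model.baseline_rate * timing.gate_time  # counts per point per scan
    lam = mean_per_gate * np.stack([model.profile(grid, center=f0) for f0 in centers])
    rng = np.random.default_rng(seed)
    if per_scan:
        lam_scan = np.repeat(lam[:, None, :], timing.scans_per_window, axis=1)
        counts = lam_scan if noiseless else rng.poisson(lam_scan)
    else:
        lam_win = lam * timing.scans_per_window
        counts = lam_win if noiseless else rng.poisson(lam_win)
    meta = {
        "kappa_khz_per_C": kappa,
        "reference_temperature_C": t_ref,
        "seed": seed,
        "noiseless": noiseless,
    }
    return OdmrTimeSeries(
        frequency_grid=grid,
        counts=counts,
        scans_per_window=timing.scans_per_window,
        scan_time=timing.scan_time,
        window_time=timing.window_time,
        duty_cycle_period=timing.duty_cycle_period,
        gate_time=timing.gate_time,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# RTD resistance traces


def generate_rtd_trace(
    T_profile: TemperatureProfile,
    times: np.ndarray,
    R0: float = 100.0,
    T0: float = 21.0,
    eta_rtd: float = 2.44e-3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Resistance series R(T) = R0*(1 + eta_rtd*(T - T0)) + Gaussian noise.

    Inverse of the linear RTD conversion used by `rtd_to_temperature`;
    eta_rtd is the fractional resistance change per degC of the gold track.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    times = np.asarray(times, dtype=float)
    temps = _as_profile(T_profile)(times)
    resistance = R0 * (1.0 + eta_rtd * (temps - T0))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resistance = resistance + rng.normal(scale=noise_sd, size=resistance.shape)
    return resistance


# ---------------------------------------------------------------------------
# double-plane orbital tracker


@dataclass
class TrackerConfig:
    """Geometry, photon budget and feedback gains of the orbital tracker.

    The excitation beam orbits the last inferred particle position with a
    50 nm radius while two collection planes offset axially by +-50 nm
    (100 nm separation) record photoluminescence.  The first Fourier
    harmonic of counts around the orbit drives the transverse correction,
    the top/bottom imbalance the axial one.
    """

    orbit_radius: float = 50.0  # nm
    plane_separation: float = 100.0  # nm
    orbit_period: float = DEFAULT_SAMPLING_PERIOD  # s
    psf_radius: float = 250.0  # nm, transverse 1/e^2 radius
    psf_axial_radius: float = 600.0  # nm, axial 1/e^2 half-length
    emitter_rate: float = 1e6  # counts/s, both planes summed
    points_per_orbit: int = 64
    gain_xy: float = 1.0
    gain_z: float = 0.5

    def __post_init__(self) -> None:
        for name in ("orbit_radius", "plane_separation", "orbit_period",
                     "psf_radius", "psf_axial_radius", "emitter_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.points_per_orbit < 4:
            raise ValueError("points_per_orbit must be >= 4")
        for g in (self.gain_xy, self.gain_z):
            if not 0.0 < g <= 2.0:
                raise ValueError("gains must be in (0, 2]")


def simulate_tracker(
    true_trajectory: Trajectory,
    config: TrackerConfig | None = None,
    seed: int = 0,
    shot_noise: bool = True,
) -> tuple[Trajectory, np.ndarray]:
    """Run the double-plane orbital tracking feedback on a known trajectory.

    Per orbit, Poisson counts are sampled along the orbit in both offset
    planes from a Gaussian point-spread function centered on the true
    particle position.  The transverse correction comes from the first
    Fourier harmonic of the counts around the orbit, the axial correction
    from the log-imbalance of the two planes, each scaled by its gain.
    With `shot_noise=False` the expected counts are used directly, giving
    the noiseless feedback fixed point.

    Returns the tracker-reported trajectory (sampled once per orbit) and
    the per-update tracking error in nm.  A particle farther than
    3*psf_radius from the tracker is flagged as lost in the reported
    trajectory's meta (tracking continues, errors keep being recorded).
    """
    config = config or TrackerConfig()
    if true_trajectory.sampling_period > config.orbit_period * (1 + 1e-9):
        raise ValueError("true trajectory must be sampled at least as finely as orbit_period")
    rng = np.random.default_rng(seed)

    n_orbits = int(np.floor(true_trajectory.duration / config.orbit_period)) + 1
    sample_idx = np.clip(
        np.round(np.arange(n_orbits) * config.orbit_period / true_trajectory.sampling_period).astype(int),
        0, len(true_trajectory) - 1,
    )
    true_pos = true_trajectory.positions[sample_idx]

    theta = 2.0 * np.pi * np.arange(config.points_per_orbit) / config.points_per_orbit
    orbit_xy = config.orbit_radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    dwell = config.orbit_period / config.points_per_orbit
    rate_per_plane = config.emitter_rate / 2.0
    w2 = config.psf_radius**2
    wz2 = config.psf_axial_radius**2
    half_sep = config.plane_separation / 2.0

    center = true_pos[0].copy()  # tracker initialized on the particle
    reported = np.empty_like(true_pos)
    errors = np.empty(n_orbits)
    lost_at: int | None = None

    for k in range(n_orbits):
        delta = true_pos[k] - center
        beam_xy = orbit_xy - delta[:2]  # beam position relative to particle, per point
        radial2 = np.einsum("ij,ij->i", beam_xy, beam_xy)
        transverse = np.exp(-2.0 * radial2 / w2)
        lam = np.empty((2, config.points_per_orbit))
        for p, z_off in enumerate((half_sep, -half_sep)):
            axial = np.exp(-2.0 * (z_off - delta[2]) ** 2 / wz2)
            lam[p] = rate_per_plane * dwell * transverse * axial
        counts = rng.poisson(lam).astype(float) if shot_noise else lam

        total = counts.sum()
        if total > 0:
            ring = counts.sum(axis=0)
            est_x = (w2 / (2.0 * config.orbit_radius)) * (ring @ np.cos(theta)) / total
            est_y = (w2 / (2.0 * config.orbit_radius)) * (ring @ np.sin(theta)) / total
            center[0] += config.gain_xy * est_x
            center[1] += config.gain_xy * est_y
            n_top, n_bot = counts.sum(axis=1)
            if n_top > 0 and n_bot > 0:
                est_z = (wz2 / (8.0 * half_sep)) * np.log(n_top / n_bot)
                center[2] += config.gain_z * est_z
        reported[k] = center
        errors[k] = np.linalg.norm(center - true_pos[k])
        if lost_at is None and errors[k] > 3.0 * config.psf_radius:
            lost_at = k
            warnings.warn(f"particle lost at orbit {k}: error {errors[k]:.0f} nm", stacklevel=2)

    meta = {
        "generator": "tracker",
        "seed": seed,
        "shot_noise": shot_noise,
        "lost_at_orbit": lost_at,
    }
    reported_traj = Trajectory(
        times=np.arange(n_orbits) * config.orbit_period,
        positions=reported,
        sampling_period=config.orbit_period,
        localization_sigma=0.0,
        meta=meta,
    )
    return reported_traj, errors
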