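"""Directed-motion segmentation and anomalous-exponent analysis.

Trajectories are scanned with a sliding window; windows whose
directionality ratio gamma = displacement / path length exceeds a
Monte-Carlo Brownian null threshold are merged into directed segments,
the remainder labeled nondirected.  Per-segment anomalous exponents
alpha come from log-log regression of the time-averaged MSD
(MSD proportional to tau^alpha), and ensembles of exponents are
summarized by a normal fit with sub/diffusive/superdiffusive fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rheometry import MsdCurve, compute_msd
from .trajectory import Trajectory

TRANSVERSE = ("x", "y")


@dataclass
class MotionSegment:
    """A labeled trajectory interval [start_index, end_index)."""

    start_index: int
    end_index: int
    gamma: float
    displacement: float  # nm
    path_length: float  # nm
    label: str  # "directed" | "nondirected"
    alpha: float = np.nan
    alpha_se: float = np.nan
    stationary: bool = False  # zero path length; gamma defined as 0


@dataclass
class AlphaDistribution:
    """Normal fit and diffusive-class fractions of an exponent sample."""

    alphas: np.ndarray
    fitted_mean: float
    fitted_sd: float
    class_fractions: dict[str, float]  # sub / diffusive / super


# ---------------------------------------------------------------------------
# directionality ratio


def directionality_ratio(
    traj: Trajectory, start: int, end: int, axes: tuple[str, ...] = TRANSVERSE
) -> float:
    """gamma = |r(end-1) - r(start)| / sum of step lengths over [start, end).

    Computed in the transverse plane by default.  A stationary window
    (zero path length) returns gamma = 0 with a warning.
    """
    if end - start < 3:
        raise ValueError("window must span at least 2 steps")
    pos = traj.axis_columns(axes)[start:end]
    return _gamma_of_window(pos)


def _gamma_of_window(pos: np.ndarray) -> float:
    steps = np.diff(pos, axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    if path == 0.0:
        warnings.warn("stationary window: gamma defined as 0", stacklevel=3)
        return 0.0
    disp = float(np.linalg.norm(pos[-1] - pos[0]))
    return disp / path


def _sliding_gamma(pos: np.ndarray, window: int) -> np.ndarray:
    """gamma for every window of `window` steps (window+1 samples)."""
    steps = np.diff(pos, axis=0)
    lens = np.linalg.norm(steps, axis=1)
    cum_len = np.concatenate([[0.0], np.cumsum(lens)])
    n_win = pos.shape[0] - window
    starts = np.arange(n_win)
    path = cum_len[starts + window] - cum_len[starts]
    disp = np.linalg.norm(pos[starts + window] - pos[starts], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(path > 0, disp / np.where(path == 0, 1, path), 0.0)
    return gamma


# ---------------------------------------------------------------------------
# Brownian null threshold


def gamma_null_threshold(
    D: float,
    window: int,
    dt: float,
    quantile: float = 0.99,
    n_sim: int = 10_000,
    seed: int = 0,
    localization_sigma: float = 0.0,
) -> float:
    """Monte-Carlo quantile of gamma over Brownian windows (the null).

    Simulates `n_sim` independent transverse Brownian windows of `window`
    steps with diffusion coefficient `D` and returns the requested
    quantile of their directionality ratios.  For pure Brownian motion
    gamma is scale-free, but a matched D matters once localization noise
    is included.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a stable quantile")
    if window < 3:
        raise ValueError("window must be >= 3 steps")
    rng = np.random.default_rng(seed)
    inc = rng.normal(scale=np.sqrt(2.0 * D * dt), size=(n_sim, window, 2))
    pos = np.concatenate([np.zeros((n_sim, 1, 2)), np.cumsum(inc, axis=1)], axis=1)
    if localization_sigma > 0:
        pos = pos + rng.normal(scale=localization_sigma, size=pos.shape)
    steps = np.diff(pos, axis=1)
    path = np.linalg.norm(steps, axis=2).sum(axis=1)
    disp = np.linalg.norm(pos[:, -1] - pos[:, 0], axis=1)
    gamma = disp / path
    return float(np.quantile(gamma, quantile))


# ---------------------------------------------------------------------------
# segmentation


def _merge_runs(flags: np.ndarray, merge_gap: int, min_duration: int) -> list[tuple[int, int]]:
    """Half-open index runs of True after gap-merging and minimum-length culling."""
    idx = np.nonzero(flags)[0]
    if idx.size == 0:
        return []
    runs: list[list[int]] = [[idx[0], idx[0] + 1]]
    for i in idx[1:]:
        if i - runs[-1][1] < merge_gap:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1])
    return [(a, b) for a, b in runs if b - a >= min_duration]


def segment_trajectory(
    traj: Trajectory,
    window: int = 50,
    gamma_star: float | None = None,
    min_duration: int = 10,
    merge_gap: int = 3,
    quantile: float = 0.99,
    n_sim: int = 10_000,
    seed: int = 0,
    axes: tuple[str, ...] = TRANSVERSE,
) -> list[MotionSegment]:
    """Split a trajectory into directed and nondirected segments.

    A sliding window of `window` steps computes gamma at every start
    index; windows above `gamma_star` (computed from the matched Brownian
    null at `quantile` when not given) are merged into directed runs.
    Runs shorter than `min_duration` windows are discarded and runs
    separated by fewer than `merge_gap` windows are joined, suppressing
    single-window flickers.  Each segment carries its own gamma and, when
    long enough, a fitted anomalous exponent.
    """
    if window < 3:
        raise ValueError("window must be >= 3 steps")
    pos = traj.axis_columns(axes)
    n = pos.shape[0]
    if n <= window:
        return [_make_segment(traj, 0, n, "nondirected", axes)]
    if gamma_star is None:
        d_guess = _increment_diffusivity(pos, traj.sampling_period)
        gamma_star = gamma_null_threshold(
            d_guess, window, traj.sampling_period, quantile=quantile,
            n_sim=n_sim, seed=seed, localization_sigma=traj.localization_sigma,
        )
    gamma = _sliding_gamma(pos, window)
    runs = _merge_runs(gamma > gamma_star, merge_gap=merge_gap, min_duration=min_duration)

    segments: list[MotionSegment] = []
    cursor = 0
    for w_start, w_end in runs:
        s, e = w_start, w_end + window  # window run -> sample interval
        if s > cursor:
            segments.append(_make_segment(traj, cursor, s + 1, "nondirected", axes))
        segments.append(_make_segment(traj, s, e, "directed", axes))
        cursor = e - 1  # segments share a boundary sample for contiguity of steps
    if cursor < n - 1:
        segments.append(_make_segment(traj, cursor, n, "nondirected", axes))
    return segments


def _increment_diffusivity(pos: np.ndarray, dt: float) -> float:
    """Crude per-axis D estimate from single-step increments, for the null."""
    inc = np.diff(pos, axis=0)
    return float(np.mean(inc**2) / (2.0 * dt))


def _make_segment(
    traj: Trajectory, start: int, end: int, label: str, axes: tuple[str, ...]
) -> MotionSegment:
    pos = traj.axis_columns(axes)[start:end]
    steps = np.diff(pos, axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    disp = float(np.linalg.norm(pos[-1] - pos[0])) if pos.shape[0] > 1 else 0.0
    stationary = path == 0.0
    gamma = 0.0 if stationary else disp / path
    seg = MotionSegment(
        start_index=start, end_index=end, gamma=gamma,
        displacement=disp, path_length=path, label=label, stationary=stationary,
    )
    length = end - start
    if length >= 20 and not stationary:
        sub = Trajectory(
            times=traj.times[start:end],
            positions=traj.positions[start:end],
            sampling_period=traj.sampling_period,
            localization_sigma=traj.localization_sigma,
            noise_floor=traj.noise_floor,
        )
        msd = compute_msd(sub, axes=axes)
        try:
            seg.alpha, seg.alpha_se = fit_alpha(msd)
        except ValueError:
            pass
    return seg


# ---------------------------------------------------------------------------
# anomalous exponent


def fit_alpha(
    msd: MsdCurve,
    lag_range: tuple[float, float] | None = None,
    min_lag_steps: int = 2,
    n_per_decade: int = 16,
) -> tuple[float, float]:
    """Anomalous exponent from ln MSD vs ln tau least squares.

    Lags are restricted to `lag_range` (default: from 2 samples up to the
    curve's maximum, which `compute_msd` already caps at N/4) and
    subsampled to a log-spaced grid so each decade of lag contributes
    equal weight; noise-floor-dominated points are excluded.  Returns
    (alpha, regression standard error).
    """
    dt = msd.lags[0]  # first lag is one sampling period
    lo = min_lag_steps * dt if lag_range is None else lag_range[0]
    hi = msd.lags[-1] if lag_range is None else lag_range[1]
    sel = (msd.lags >= lo * (1 - 1e-9)) & (msd.lags <= hi * (1 + 1e-9))
    sel &= msd.msd > 0
    usable = sel & ~msd.below_noise
    if usable.sum() < 4:
        if sel.sum() >= 4:
            warnings.warn("fitting alpha on noise-floor-dominated lags", stacklevel=2)
            usable = sel
        else:
            raise ValueError("need at least 4 usable lags to fit alpha")
    lags = msd.lags[usable]
    vals = msd.msd[usable]
    n_decades = max(np.log10(lags[-1] / lags[0]), 1e-6)
    n_pts = max(int(np.ceil(n_decades * n_per_decade)) + 1, 4)
    idx = np.unique(np.searchsorted(lags, np.geomspace(lags[0], lags[-1], n_pts)).clip(0, lags.size - 1))
    x, y = np.log(lags[idx]), np.log(vals[idx])
    coef, cov = np.polyfit(x, y, 1, cov=True)
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


def summarize_alphas(alphas: np.ndarray, diffusive_band: float = 0.1) -> AlphaDistribution:
    """Maximum-likelihood normal fit plus motion-class fractions.

    Classes: subdiffusive alpha < 1 - band, diffusive within the band
    around 1, superdiffusive alpha > 1 + band.  The band is a reporting
    convenience; the underlying classification boundary is alpha = 1.
    """
    alphas = np.asarray(alphas, dtype=float)
    alphas = alphas[np.isfinite(alphas)]
    if alphas.size < 3:
        raise ValueError("need at least 3 exponents")
    mean = float(alphas.mean())
    sd = float(alphas.std(ddof=0))
    n = alphas.size
    fractions = {
        "sub": float(np.mean(alphas < 1.0 - diffusive_band)),
        "diffusive": float(np.mean(np.abs(alphas - 1.0) <= diffusive_band)),
        "super": float(np.mean(alphas > 1.0 + diffusive_band)),
    }
    assert abs(sum(fractions.values()) - 1.0) < 1e-9
    return AlphaDistribution(alphas=alphas, fitted_mean=mean, fitted_sd=sd,
                             class_fractions=fractions)
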