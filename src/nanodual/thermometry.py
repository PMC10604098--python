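"""ODMR thermometry: interpolation shift fitting, Allan-deviation
sensitivity, the shot-noise Cramér-Rao benchmark, and RTD conversion.

The frequency-shift estimator follows the interpolation method: the mean
spectrum of the whole record defines a piecewise-linear template; each
400 ms bin (two duty-cycle windows) is then fit against the template
evaluated at shifted frequencies, with a free amplitude and offset to
absorb photoluminescence drift.  Shifts convert to temperature through
the thermal slope kappa of the NV resonance (default -60.0 kHz/degC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .synthetic import OdmrTimeSeries, SpectrumModel

# ---------------------------------------------------------------------------
# calibrations


@dataclass
class ThermometryCalibration:
    """Thermal response of the ODMR center frequency."""

    kappa: float = -60.0  # kHz/degC
    reference_frequency: float = 2870.0  # MHz
    reference_temperature: float = 35.0  # degC

    def __post_init__(self) -> None:
        if self.kappa == 0:
            raise ValueError("kappa must be nonzero for temperature conversion")


@dataclass
class RtdCalibration:
    """Linear resistance-temperature calibration of the gold RTD track."""

    R0: float = 100.0  # Ohm at T0_rtd
    T0_rtd: float = 21.0  # degC
    eta_rtd: float = 2.44e-3  # fractional resistance change per degC

    def __post_init__(self) -> None:
        if self.R0 <= 0 or self.eta_rtd <= 0:
            raise ValueError("R0 and eta_rtd must be positive")


def rtd_to_temperature(R: float | np.ndarray, cal: RtdCalibration) -> float | np.ndarray:
    """Convert RTD resistance (Ohm) to temperature: T = T0 + (R/R0 - 1)/eta."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("resistance must be positive")
    out = cal.T0_rtd + (R / cal.R0 - 1.0) / cal.eta_rtd
    return float(out) if out.ndim == 0 else out


def shift_to_temperature(
    delta_f: float | np.ndarray,
    cal: ThermometryCalibration,
    se: float | np.ndarray | None = None,
):
    """Convert a frequency shift in kHz to a temperature change in degC.

    dT = delta_f / kappa; a standard error propagates as |se / kappa|.
    """
    dT = np.asarray(delta_f, dtype=float) / cal.kappa
    dT = float(dT) if dT.ndim == 0 else dT
    if se is None:
        return dT
    se_t = np.abs(np.asarray(se, dtype=float) / cal.kappa)
    return dT, (float(se_t) if np.ndim(se_t) == 0 else se_t)


# ---------------------------------------------------------------------------
# interpolation shift fitting


@dataclass
class InterpolationTemplate:
    """Piecewise-linear ODMR template, normalized to unit mean."""

    frequency_grid: np.ndarray  # MHz
    template_values: np.ndarray  # dimensionless, unit mean
    construction_window: slice = field(default_factory=lambda: slice(None))

    def __call__(self, f: np.ndarray) -> np.ndarray:
        """Evaluate by linear interpolation (edge values held outside grid)."""
        return np.interp(f, self.frequency_grid, self.template_values)


def build_template(
    series: OdmrTimeSeries, window_slice: slice = slice(None)
) -> InterpolationTemplate:
    """Template = mean spectrum over all (selected) scans, unit-mean normalized."""
    mean_spec = series.mean_spectrum(window_slice)
    total = mean_spec.mean()
    if total <= 0:
        raise ValueError("cannot build a template from all-zero counts")
    return InterpolationTemplate(
        frequency_grid=series.frequency_grid.copy(),
        template_values=mean_spec / total,
        construction_window=window_slice,
    )


@dataclass
class FrequencyShiftSeries:
    """Per-bin ODMR frequency shifts (kHz) with standard errors."""

    bin_times: np.ndarray  # s, left edge of each bin
    shifts: np.ndarray  # kHz
    standard_errors: np.ndarray  # kHz
    n_f: int = 1  # how many raw shifts each entry averages
    out_of_range: np.ndarray | None = None  # bool flags per bin

    def __post_init__(self) -> None:
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        if self.out_of_range is None:
            self.out_of_range = np.zeros(self.shifts.size, dtype=bool)


def _shift_candidates(series: OdmrTimeSeries, max_shift: float | None) -> np.ndarray:
    grid = series.frequency_grid
    spacing = float(np.mean(np.diff(grid)))
    span = float(grid[-1] - grid[0])
    if max_shift is None:
        max_shift = span / 4.0
    step = spacing / 10.0  # grid-search resolution before parabolic refinement
    return np.arange(-max_shift, max_shift + step / 2.0, step)


def _sse_matrix(
    bins: np.ndarray, template: InterpolationTemplate, candidates: np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    """SSE of each (bin, candidate shift) under free amplitude and offset.

    For spectrum y and shifted template u the model is y ~ a*u + b; the
    minimized SSE is Syy - Suy^2/Suu with centered variables, computed for
    all bins and shifts at once.
    """
    u = np.stack([template(grid - s) for s in candidates])  # (S, P)
    u_c = u - u.mean(axis=1, keepdims=True)
    suu = np.einsum("sp,sp->s", u_c, u_c)
    y_c = bins - bins.mean(axis=1, keepdims=True)
    syy = np.einsum("bp,bp->b", y_c, y_c)
    suy = y_c @ u_c.T  # (B, S)
    return syy[:, None] - suy**2 / suu[None, :]


def _parabolic_refine(candidates: np.ndarray, sse: np.ndarray):
    """Vectorized 3-point parabola through each row's SSE minimum.

    Returns refined shift, SSE curvature (d2 SSE / d shift^2) and the
    minimum SSE per row.  Rows whose minimum sits on the grid edge keep the
    edge value with zero curvature (flagged upstream).
    """
    idx = np.argmin(sse, axis=1)
    edge = (idx == 0) | (idx == sse.shape[1] - 1)
    idx_c = np.clip(idx, 1, sse.shape[1] - 2)
    rows = np.arange(sse.shape[0])
    s0 = sse[rows, idx_c - 1]
    s1 = sse[rows, idx_c]
    s2 = sse[rows, idx_c + 1]
    step = candidates[1] - candidates[0]
    denom = s0 - 2 * s1 + s2
    offset = np.where(denom > 0, 0.5 * (s0 - s2) / np.where(denom == 0, 1, denom), 0.0)
    offset = np.clip(offset, -1.0, 1.0)
    shift = candidates[idx_c] + offset * step
    shift = np.where(edge, candidates[idx], shift)
    curvature = np.where(denom > 0, denom / step**2, 0.0)
    sse_min = s1 - 0.25 * (s0 - s2) * offset
    return shift, curvature, sse_min, edge


def fit_frequency_shifts(
    series: OdmrTimeSeries,
    template: InterpolationTemplate,
    windows_per_bin: int = 2,
    max_shift: float | None = None,
) -> FrequencyShiftSeries:
    """Fit the frequency shift of every bin against the template.

    Bins are consecutive groups of `windows_per_bin` duty-cycle windows
    (default 2 windows = 400 ms of data).  Each bin's mean spectrum is fit
    to the template evaluated at f - delta_f with free amplitude and
    offset: a coarse grid search at one tenth of the grid spacing is
    followed by a three-point parabolic refinement.  Shifts beyond a
    quarter of the grid span are flagged out-of-range.
    """
    win = series.window_counts().astype(float)
    n_bins = win.shape[0] // windows_per_bin
    if n_bins < 1:
        raise ValueError("series shorter than one bin")
    bins = win[: n_bins * windows_per_bin].reshape(n_bins, windows_per_bin, -1).mean(axis=1)

    grid = series.frequency_grid
    candidates = _shift_candidates(series, max_shift)
    sse = _sse_matrix(bins, template, candidates, grid)
    shift_mhz, curvature, sse_min, edge = _parabolic_refine(candidates, sse)

    # SE from the local SSE curvature: var(shift) ~ 2*sigma_res^2 / SSE''
    n_pts = grid.size
    dof = max(n_pts - 3, 1)
    sigma2 = sse_min / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se_mhz = np.sqrt(np.where(curvature > 0, 2.0 * sigma2 / curvature, np.inf))

    span = float(grid[-1] - grid[0])
    out_of_range = edge | (np.abs(shift_mhz) > span / 4.0)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(out_of_range.sum())} bins have out-of-range frequency shifts",
            stacklevel=2,
        )
    bin_period = windows_per_bin * series.duty_cycle_period
    return FrequencyShiftSeries(
        bin_times=np.arange(n_bins) * bin_period,
        shifts=shift_mhz * c.MHZ_TO_KHZ,
        standard_errors=se_mhz * c.MHZ_TO_KHZ,
        n_f=1,
        out_of_range=out_of_range,
    )


def fit_frequency_shift(
    bin_counts: np.ndarray,
    template: InterpolationTemplate,
    frequency_grid: np.ndarray | None = None,
    max_shift: float | None = None,
) -> tuple[float, float]:
    """Fit a single bin's mean spectrum against the template.

    `bin_counts` is the spectrum (counts per frequency point) of one 400 ms
    bin.  Returns (shift, se) in kHz.
    """
    grid = template.frequency_grid if frequency_grid is None else np.asarray(frequency_grid)
    y = np.atleast_2d(np.asarray(bin_counts, dtype=float))
    spacing = float(np.mean(np.diff(grid)))
    span = float(grid[-1] - grid[0])
    if max_shift is None:
        max_shift = span / 4.0
    step = spacing / 10.0
    candidates = np.arange(-max_shift, max_shift + step / 2.0, step)
    sse = _sse_matrix(y, template, candidates, grid)
    shift, curvature, sse_min, edge = _parabolic_refine(candidates, sse)
    if edge[0] or abs(shift[0]) > span / 4.0:
        warnings.warn("fitted shift is out of range", stacklevel=2)
    dof = max(grid.size - 3, 1)
    se = np.sqrt(2.0 * sse_min[0] / dof / curvature[0]) if curvature[0] > 0 else np.inf
    return float(shift[0] * c.MHZ_TO_KHZ), float(se * c.MHZ_TO_KHZ)


def average_shifts(series: FrequencyShiftSeries, n_f: int = 25) -> FrequencyShiftSeries:
    """Average non-overlapping blocks of n_f consecutive shifts.

    Each block is replaced by its mean with the standard error of the n_f
    shifts; a trailing partial block is dropped with a warning.
    """
    if n_f < 2:
        raise ValueError("n_f must be >= 2 (standard error undefined otherwise)")
    n_blocks = series.shifts.size // n_f
    if n_blocks == 0:
        raise ValueError(f"need at least {n_f} shifts, have {series.shifts.size}")
    dropped = series.shifts.size - n_blocks * n_f
    if dropped:
        warnings.warn(f"dropping trailing partial block of {dropped} shifts", stacklevel=2)
    blocks = series.shifts[: n_blocks * n_f].reshape(n_blocks, n_f)
    means = blocks.mean(axis=1)
    ses = blocks.std(axis=1, ddof=1) / np.sqrt(n_f)
    times = series.bin_times[: n_blocks * n_f : n_f]
    oor = series.out_of_range[: n_blocks * n_f].reshape(n_blocks, n_f).any(axis=1)
    return FrequencyShiftSeries(
        bin_times=times, shifts=means, standard_errors=ses, n_f=n_f, out_of_range=oor
    )


# ---------------------------------------------------------------------------
# Allan deviation and sensitivity


def overlapping_allan_deviation(
    y: np.ndarray, sample_period: float, m_list: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping Allan deviation of a regularly sampled series.

    Returns (taus, adev) over octave-spaced averaging factors by default.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 samples for an Allan deviation")
    if m_list is None:
        m_list = 2 ** np.arange(0, int(np.floor(np.log2(n / 3))) + 1)
    m_list = np.asarray(m_list, dtype=int)
    cum = np.concatenate([[0.0], np.cumsum(y)])
    taus, adevs = [], []
    for m in m_list:
        if 2 * m >= n:
            continue
        avg = (cum[m:] - cum[:-m]) / m  # means of length-m blocks at every offset
        d = avg[m:] - avg[:-m]
        adevs.append(np.sqrt(0.5 * np.mean(d * d)))
        taus.append(m * sample_period)
    return np.asarray(taus), np.asarray(adevs)


@dataclass
class SensitivityReport:
    """Allan-deviation sensitivity versus the shot-noise Cramér-Rao bound."""

    taus: np.ndarray  # s
    allan_deviation: np.ndarray  # K
    sensitivity: float  # K/sqrt(Hz)
    crb_sensitivity: float | None = None  # K/sqrt(Hz)
    white_noise_region: np.ndarray | None = None  # bool mask over taus
    white_noise_found: bool = True

    @property
    def relative_excess(self) -> float | None:
        if self.crb_sensitivity is None or not np.isfinite(self.crb_sensitivity):
            return None
        return self.sensitivity / self.crb_sensitivity - 1.0


def allan_sensitivity(
    temperature_trace: np.ndarray,
    sample_period: float,
    slope_tolerance: float = 0.1,
    fit_points: int = 4,
) -> SensitivityReport:
    """Temperature sensitivity from the Allan deviation of a trace.

    The white-noise region is identified by sliding log-log fits over
    `fit_points` consecutive octave points, accepting windows whose slope
    is within `slope_tolerance` of -1/2; the sensitivity is the average of
    adev(tau)*sqrt(tau) over the accepted points, weighted by the number
    of independent differences each deviation averages (large-tau points
    carry few degrees of freedom and would otherwise dominate the
    scatter).  If no window qualifies the report is flagged and the
    smallest-tau estimate is reported without extrapolation.
    """
    taus, adev = overlapping_allan_deviation(temperature_trace, sample_period)
    if np.all(adev == 0):
        return SensitivityReport(taus, adev, 0.0, white_noise_found=True,
                                 white_noise_region=np.ones(taus.size, bool))
    mask = np.zeros(taus.size, dtype=bool)
    log_t, log_a = np.log(taus), np.log(np.where(adev > 0, adev, np.nan))
    k = min(fit_points, taus.size)
    for i in range(taus.size - k + 1):
        seg = slice(i, i + k)
        if np.any(~np.isfinite(log_a[seg])):
            continue
        slope = np.polyfit(log_t[seg], log_a[seg], 1)[0]
        if abs(slope + 0.5) <= slope_tolerance:
            mask[seg] = True
    found = bool(mask.any())
    use = mask if found else (np.arange(taus.size) == 0)
    n = np.asarray(temperature_trace).size
    m = np.round(taus / sample_period)
    dof = np.maximum(n / m - 1.0, 1.0)  # independent two-sample differences
    w = dof[use]
    sensitivity = float(np.sum(w * adev[use] * np.sqrt(taus[use])) / np.sum(w))
    return SensitivityReport(
        taus=taus,
        allan_deviation=adev,
        sensitivity=sensitivity,
        white_noise_region=mask,
        white_noise_found=found,
    )


def cramer_rao_sensitivity(
    model: SpectrumModel,
    series: OdmrTimeSeries,
    cal: ThermometryCalibration,
) -> float:
    """Shot-noise-limited temperature sensitivity in K/sqrt(Hz).

    Fisher information for the dip center from Poisson counts,
    I = sum_i (d lambda_i / d f0)^2 / lambda_i per 2 ms scan, accumulated
    over the 80 scans collected in each 200 ms duty cycle (the 40 ms off
    time is dead time and enters through the duty-cycle period).  The
    frequency bound converts to temperature via |kappa|.
    """
    grid = series.frequency_grid
    f0 = model.center_frequency
    mean_per_gate = model.baseline_rate * series.gate_time
    df = 1e-4  # MHz, numerical derivative step well below the linewidth
    lam = mean_per_gate * model.profile(grid, center=f0)
    dlam = mean_per_gate * (
        model.profile(grid, center=f0 + df) - model.profile(grid, center=f0 - df)
    ) / (2 * df)
    fisher_scan = np.sum(dlam**2 / lam)  # 1/MHz^2 per scan
    if fisher_scan == 0:
        return np.inf
    fisher_per_second = fisher_scan * series.scans_per_window / series.duty_cycle_period
    sigma_f_mhz_rt_s = 1.0 / np.sqrt(fisher_per_second)  # MHz * sqrt(s)
    return float(sigma_f_mhz_rt_s * c.MHZ_TO_KHZ / abs(cal.kappa))


def sensitivity_report(
    temperature_trace: np.ndarray,
    sample_period: float,
    model: SpectrumModel,
    series: OdmrTimeSeries,
    cal: ThermometryCalibration,
) -> SensitivityReport:
    """Allan sensitivity of a measured trace plus its Cramér-Rao benchmark."""
    report = allan_sensitivity(temperature_trace, sample_period)
    report.crb_sensitivity = cramer_rao_sensitivity(model, series, cal)
    return report
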