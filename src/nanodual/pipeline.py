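"""End-to-end orchestration: simulate both modalities, analyze, report.

A `RunConfig` fully determines a run: the temperature program, the medium
preset driving the particle motion, the spectrum model driving the ODMR
stream, analysis parameters and seeds.  `run_pipeline` generates the two
(independent) data streams on a shared wall clock, runs thermometry on
the spectra and rheometry/classification on the trajectory, and emits a
time-aligned dual-modality report plus per-stage CSV artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import constants as c
from . import io as nio
from .motion import segment_trajectory, summarize_alphas
from .rheometry import (
    compute_msd,
    estimate_diffusion,
    mason_modulus,
    welch_psd,
)
from .synthetic import (
    MediumModel,
    SpectrumModel,
    generate_odmr_series,
    simulate_brownian_varying,
    simulate_fbm,
    stokes_einstein_diffusion,
)
from .thermometry import (
    ThermometryCalibration,
    average_shifts,
    build_template,
    fit_frequency_shifts,
    shift_to_temperature,
)
from .trajectory import DEFAULT_SAMPLING_PERIOD, Trajectory

logger = logging.getLogger("nanodual")

PRESETS = ("glycerol", "gcx_like", "cell_like", "nocodazole_like")


@dataclass
class TemperatureProgram:
    """Piecewise temperature program shared by both modalities.

    kind "constant": base only. kind "square": alternates base and
    base+step every `period` seconds.  kind "steps": staircase going up
    then down in increments of `step` every `period` seconds (n_levels
    levels).
    """

    kind: str = "constant"
    base: float = 30.0  # degC
    step: float = 0.0  # degC
    period: float = 300.0  # s
    n_levels: int = 4

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.base)
        k = np.floor(t / self.period).astype(int)
        if self.kind == "square":
            return self.base + self.step * (k % 2)
        if self.kind == "steps":
            cycle = 2 * (self.n_levels - 1)
            pos = k % max(cycle, 1)
            level = np.where(pos < self.n_levels, pos, cycle - pos)
            return self.base + self.step * level
        raise ValueError(f"unknown temperature program kind {self.kind!r}")


@dataclass
class RunConfig:
    """Fully serializable description of a dual-modality run."""

    preset: str = "glycerol"
    duration: float = 120.0  # s
    temperature: TemperatureProgram = field(default_factory=TemperatureProgram)
    medium: MediumModel = field(default_factory=MediumModel)
    spectrum: SpectrumModel = field(default_factory=SpectrumModel)
    kappa: float = -60.0  # kHz/degC
    n_f: int = 25  # shifts averaged per reported temperature point
    rheology_bin: float = 30.0  # s
    readout_hz: float = 40.0
    window: int = 50  # segmentation window, steps
    quantile: float = 0.99
    seed: int = 0
    sampling_period: float = DEFAULT_SAMPLING_PERIOD
    # preset-specific knobs
    fbm_alpha: float = 0.5
    fbm_scale: float = 2e3  # nm^2/s^alpha at the base temperature
    fbm_scale_slope: float = 0.04  # fractional MSD-amplitude increase per degC
    directed_speed: float = 2000.0  # nm/s for cell_like directed intervals

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        for key, typ in (("temperature", TemperatureProgram),
                         ("medium", MediumModel), ("spectrum", SpectrumModel)):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        return cls(**data)


@dataclass
class DualModalityReport:
    """Time-aligned temperature and rheology traces from disjoint streams."""

    preset: str
    temperature_bin_times: np.ndarray  # s, left edges
    temperature_trace: np.ndarray  # degC (absolute)
    temperature_se: np.ndarray  # degC
    rheology_bin_times: np.ndarray  # s, left edges
    rheology_values: np.ndarray
    rheology_quantity: str
    rheology_units: str
    classification: dict[str, Any] | None = None
    seeds: dict[str, int] = field(default_factory=dict)
    reference_temperature: float = 0.0

    def to_dict(self) -> dict[str, Any]:
        out = {
            "preset": self.preset,
            "seeds": self.seeds,
            "temperature": {
                "bin_times_s": self.temperature_bin_times.tolist(),
                "dT_C": (self.temperature_trace - self.reference_temperature).tolist(),
                "se_C": self.temperature_se.tolist(),
                "reference_C": self.reference_temperature,
            },
            "rheology": {
                "bin_times_s": self.rheology_bin_times.tolist(),
                "values": self.rheology_values.tolist(),
                "quantity": self.rheology_quantity,
                "units": self.rheology_units,
            },
            "alignment": {
                "temperature_bin_s": float(np.diff(self.temperature_bin_times)[0])
                if self.temperature_bin_times.size > 1 else 0.0,
                "rheology_bin_s": float(np.diff(self.rheology_bin_times)[0])
                if self.rheology_bin_times.size > 1 else 0.0,
                "span_s": float(
                    max(self.temperature_bin_times[-1] if self.temperature_bin_times.size else 0,
                        self.rheology_bin_times[-1] if self.rheology_bin_times.size else 0)
                ),
            },
        }
        if self.classification is not None:
            out["classification"] = self.classification
        return out


# ---------------------------------------------------------------------------
# trajectory presets


def _preset_trajectory(config: RunConfig, n_steps: int, seed: int) -> Trajectory:
    dt = config.sampling_period
    prog = config.temperature
    if config.preset == "glycerol":
        d_of_t = lambda t: np.array(  # noqa: E731
            [stokes_einstein_diffusion(tc, config.medium) for tc in np.atleast_1d(prog(t))]
        )
        return simulate_brownian_varying(d_of_t, n_steps, dt, seed=seed)
    if config.preset == "gcx_like":
        # viscoelastic network: subdiffusive fBm whose MSD amplitude grows
        # with temperature (softening medium: |G*| drops when hot)
        temps = prog(np.arange(n_steps) * dt)
        edges = np.nonzero(np.diff(temps))[0] + 1
        bounds = np.concatenate([[0], edges, [n_steps]])
        pieces = []
        origin = np.zeros(3)
        for i in range(bounds.size - 1):
            length = bounds[i + 1] - bounds[i]
            if length < 2:
                continue
            t_seg = temps[bounds[i]]
            scale = config.fbm_scale * (
                1.0 + config.fbm_scale_slope * (t_seg - prog.base)
            )
            seg = simulate_fbm(config.fbm_alpha, scale, int(length) + 1, dt,
                               seed=seed + i)
            pieces.append(origin + seg.positions[:-1])
            origin = origin + seg.positions[-1]
        positions = np.vstack(pieces)[:n_steps]
        return Trajectory(
            times=np.arange(positions.shape[0]) * dt,
            positions=positions,
            sampling_period=dt,
            meta={"generator": "gcx_like", "seed": seed},
        )
    if config.preset == "cell_like":
        # Brownian background with a directed interval in the middle third
        base = simulate_brownian_varying(
            lambda t: np.full(np.atleast_1d(t).size,
                              stokes_einstein_diffusion(prog.base, config.medium)),
            n_steps, dt, seed=seed)
        i0, i1 = n_steps // 3, 2 * n_steps // 3
        drift = np.zeros((n_steps, 3))
        ramp = (np.arange(i1 - i0) + 1) * dt * config.directed_speed
        drift[i0:i1, 0] = ramp
        drift[i1:, 0] = ramp[-1]
        return Trajectory(
            times=base.times, positions=base.positions + drift,
            sampling_period=dt, localization_sigma=base.localization_sigma,
            meta={"generator": "cell_like", "seed": seed,
                  "directed_interval": [int(i0), int(i1)]},
        )
    # nocodazole_like: microtubule transport suppressed; weak-gel subdiffusion
    return simulate_fbm(0.3, config.fbm_scale, n_steps, dt, seed=seed)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> DualModalityReport:
    """Simulate and analyze one dual-modality run.

    The ODMR stream and the trajectory are generated from independent
    random seeds on a shared wall clock; the report aligns the binned
    temperature trace with the binned rheology trace.  When `outdir` is
    given, every stage artifact (trajectory CSV, ODMR CSV, temperature
    trace, rheology trace, report JSON, config echo) is written there.
    """
    t_start = time.time()
    seeds = {"odmr": config.seed * 1000 + 1, "trajectory": config.seed * 1000 + 2}
    prog = config.temperature
    cal = ThermometryCalibration(
        kappa=config.kappa,
        reference_frequency=config.spectrum.center_frequency,
        reference_temperature=prog.base,
    )

    # --- thermometry stream
    stage = "odmr-simulate"
    try:
        series = generate_odmr_series(
            prog, config.spectrum, kappa=config.kappa,
            duration=config.duration, seed=seeds["odmr"],
            reference_temperature=prog.base,
        )
        stage = "thermometry"
        template = build_template(series)
        shifts = fit_frequency_shifts(series, template)
        n_f = min(config.n_f, max(shifts.shifts.size // 2, 2))
        averaged = average_shifts(shifts, n_f=n_f) if shifts.shifts.size >= 2 * n_f else shifts
        dT, se = shift_to_temperature(averaged.shifts, cal, averaged.standard_errors)
        temp_trace = prog.base + np.atleast_1d(dT)
        temp_se = np.atleast_1d(se)
        temp_times = averaged.bin_times

        # --- rheometry stream
        stage = "trajectory-simulate"
        n_steps = int(config.duration / config.sampling_period) + 1
        traj = _preset_trajectory(config, n_steps, seeds["trajectory"])
        stage = "rheometry"
        quantity, units, rheo_times, rheo_values = _binned_rheology(config, traj)

        stage = "classification"
        classification = None
        if config.preset in ("cell_like", "nocodazole_like"):
            segments = segment_trajectory(
                traj, window=config.window, quantile=config.quantile,
                seed=config.seed * 1000 + 3,
            )
            alphas = [s.alpha for s in segments if np.isfinite(s.alpha)]
            classification = {
                "segments": [
                    {"start_s": float(traj.times[s.start_index]),
                     "end_s": float(traj.times[s.end_index - 1]),
                     "label": s.label, "gamma": s.gamma,
                     "alpha": None if not np.isfinite(s.alpha) else s.alpha}
                    for s in segments
                ],
                "n_directed": sum(s.label == "directed" for s in segments),
            }
            if len(alphas) >= 3:
                dist = summarize_alphas(np.asarray(alphas))
                classification["alpha_mean"] = dist.fitted_mean
                classification["alpha_sd"] = dist.fitted_sd
                classification["class_fractions"] = dist.class_fractions
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = DualModalityReport(
        preset=config.preset,
        temperature_bin_times=temp_times,
        temperature_trace=temp_trace,
        temperature_se=temp_se,
        rheology_bin_times=rheo_times,
        rheology_values=rheo_values,
        rheology_quantity=quantity,
        rheology_units=units,
        classification=classification,
        seeds=seeds,
        reference_temperature=prog.base,
    )
    logger.info("pipeline %s finished in %.2f s", config.preset, time.time() - t_start)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_trajectory(traj, outdir / "trajectory.csv")
        nio.write_odmr(series, outdir / "odmr.csv")
        pd.DataFrame({"t_s": temp_times, "dT_C": temp_trace - prog.base,
                      "se_C": temp_se}).to_csv(outdir / "temperature.csv", index=False)
        pd.DataFrame({"t_s": rheo_times, quantity: rheo_values}).to_csv(
            outdir / "rheology.csv", index=False)
        nio.write_report(report.to_dict(), outdir / "report.json")
        (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return report


def _binned_rheology(
    config: RunConfig, traj: Trajectory
) -> tuple[str, str, np.ndarray, np.ndarray]:
    """Per-bin rheology readout: D (glycerol), |G*| (gcx), PSD@f (cell)."""
    dt = traj.sampling_period
    bin_steps = max(int(config.rheology_bin / dt), 20)
    n_bins = len(traj) // bin_steps
    if n_bins == 0:
        bin_steps = len(traj)
        n_bins = 1
    times, values = [], []
    for b in range(n_bins):
        s, e = b * bin_steps, min((b + 1) * bin_steps + 1, len(traj))
        sub = Trajectory(
            times=traj.times[s:e], positions=traj.positions[s:e],
            sampling_period=dt, localization_sigma=traj.localization_sigma,
            noise_floor=traj.noise_floor,
        )
        times.append(float(traj.times[s]))
        if config.preset == "glycerol":
            msd = compute_msd(sub)
            lag = min(1.0, msd.lags[-1])
            values.append(estimate_diffusion(msd, lag=lag).D)
        elif config.preset == "gcx_like":
            msd = compute_msd(sub)
            t_bin = config.temperature(np.array([traj.times[s]]))[0]
            mod = mason_modulus(msd, T=c.celsius_to_kelvin(t_bin),
                                radius=config.medium.particle_radius)
            mid = np.argmin(np.abs(mod.f - 2.7))
            values.append(float(mod.G_abs[mid]))
        else:
            window = min(28.8, sub.duration / 2)
            psd = welch_psd(sub, window=window, readout_frequency=config.readout_hz)
            values.append(psd.at_frequency())
    quantity = {"glycerol": "D_nm2_s", "gcx_like": "G_abs_Pa"}.get(
        config.preset, f"psd_{config.readout_hz:g}Hz_um2_per_Hz")
    units = {"glycerol": "nm^2/s", "gcx_like": "Pa"}.get(config.preset, "um^2/Hz")
    return quantity, units, np.asarray(times), np.asarray(values)
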