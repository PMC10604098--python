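"""File formats: trajectory CSV, ODMR CSV, and the dual-modality report.

Trajectories are CSV with header ``t_s,x_nm,y_nm,z_nm`` (one row per
tracking update) plus a YAML metadata sidecar (``<file>.meta.yaml``)
carrying the sampling period, seed and generator parameters.  ODMR
streams are CSV with header ``window_index,scan_index,freq_MHz,counts``
(scan_index -1 marks window-aggregated counts) plus a sidecar with the
duty-cycle timing constants.  Reports are JSON validated against a small
structural schema.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .synthetic import OdmrTimeSeries
from .trajectory import Trajectory

TRAJECTORY_COLUMNS = ["t_s", "x_nm", "y_nm", "z_nm"]
ODMR_COLUMNS = ["window_index", "scan_index", "freq_MHz", "counts"]


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending row."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_s": traj.times,
            "x_nm": traj.positions[:, 0],
            "y_nm": traj.positions[:, 1],
            "z_nm": traj.positions[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "sampling_period_s": float(traj.sampling_period),
        "localization_sigma_nm": float(traj.localization_sigma),
        "noise_floor_um2": float(traj.noise_floor),
        **{k: v for k, v in traj.meta.items()},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(TRAJECTORY_COLUMNS)}, got {','.join(df.columns)}"
        )
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        row = int(np.argwhere(~np.isfinite(values))[0, 0]) + 2  # 1-based + header
        raise FormatError(f"{path}: non-finite value at row {row}")
    dt_arr = np.diff(values[:, 0])
    if np.any(dt_arr <= 0):
        row = int(np.argmax(dt_arr <= 0)) + 3
        raise FormatError(f"{path}: non-monotonic time at row {row}")
    meta: dict[str, Any] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    sampling_period = float(meta.get("sampling_period_s", np.median(dt_arr)))
    return Trajectory(
        times=values[:, 0],
        positions=values[:, 1:4],
        sampling_period=sampling_period,
        localization_sigma=float(meta.get("localization_sigma_nm", 0.0)),
        noise_floor=float(meta.get("noise_floor_um2", 1e-4)),
        meta={k: v for k, v in meta.items()
              if k not in ("sampling_period_s", "localization_sigma_nm", "noise_floor_um2")},
    )


# ---------------------------------------------------------------------------
# ODMR streams


def write_odmr(series: OdmrTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    n_points = series.frequency_grid.size
    counts = series.counts
    if series.per_scan:
        n_windows, n_scans = counts.shape[:2]
        win_idx = np.repeat(np.arange(n_windows), n_scans * n_points)
        scan_idx = np.tile(np.repeat(np.arange(n_scans), n_points), n_windows)
        freq = np.tile(series.frequency_grid, n_windows * n_scans)
        flat = counts.reshape(-1)
    else:
        n_windows = counts.shape[0]
        win_idx = np.repeat(np.arange(n_windows), n_points)
        scan_idx = np.full(win_idx.size, -1)
        freq = np.tile(series.frequency_grid, n_windows)
        flat = counts.reshape(-1)
    pd.DataFrame(
        {"window_index": win_idx, "scan_index": scan_idx,
         "freq_MHz": freq, "counts": flat}
    ).to_csv(path, index=False, float_format="%.12g")
    meta = {
        "scans_per_window": int(series.scans_per_window),
        "scan_time_s": float(series.scan_time),
        "window_time_s": float(series.window_time),
        "duty_cycle_period_s": float(series.duty_cycle_period),
        "gate_time_s": float(series.gate_time),
        "per_scan": bool(series.per_scan),
        **{k: v for k, v in series.meta.items()},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_odmr(path: str | Path) -> OdmrTimeSeries:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ODMR_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(ODMR_COLUMNS)}, got {','.join(df.columns)}"
        )
    if (df["counts"] < 0).any():
        row = int(df.index[df["counts"] < 0][0]) + 2
        raise FormatError(f"{path}: negative counts at row {row}")
    sidecar = _sidecar_path(path)
    meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
    meta = meta or {}
    timing = {
        "scans_per_window": int(meta.get("scans_per_window", 80)),
        "scan_time": float(meta.get("scan_time_s", 2e-3)),
        "window_time": float(meta.get("window_time_s", 0.16)),
        "duty_cycle_period": float(meta.get("duty_cycle_period_s", 0.2)),
        "gate_time": float(meta.get("gate_time_s", 10e-6)),
    }
    grid = np.sort(df["freq_MHz"].unique())
    n_points = grid.size
    per_scan = bool((df["scan_index"] >= 0).any())
    windows = np.sort(df["window_index"].unique())
    if not np.array_equal(windows, np.arange(windows.size)):
        missing = sorted(set(range(int(windows.max()) + 1)) - set(windows.tolist()))
        raise FormatError(f"{path}: missing window(s) {missing}")
    if per_scan:
        n_scans = timing["scans_per_window"]
        counts = np.zeros((windows.size, n_scans, n_points), dtype=np.int64)
        grouped = df.groupby("window_index")
        for w, sub in grouped:
            scans = np.sort(sub["scan_index"].unique())
            if not np.array_equal(scans, np.arange(n_scans)):
                missing = sorted(set(range(n_scans)) - set(scans.tolist()))
                raise FormatError(
                    f"{path}: window {int(w)} is missing scan(s) {missing}"
                )
            block = sub.sort_values(["scan_index", "freq_MHz"])
            if block.shape[0] != n_scans * n_points:
                raise FormatError(f"{path}: window {int(w)} has an incomplete grid")
            counts[int(w)] = block["counts"].to_numpy().reshape(n_scans, n_points)
    else:
        counts = np.zeros((windows.size, n_points), dtype=np.int64)
        for w, sub in df.groupby("window_index"):
            if sub.shape[0] != n_points:
                raise FormatError(
                    f"{path}: window {int(w)} has {sub.shape[0]} points, expected {n_points}"
                )
            counts[int(w)] = sub.sort_values("freq_MHz")["counts"].to_numpy()
    extra = {k: v for k, v in meta.items()
             if k not in ("scans_per_window", "scan_time_s", "window_time_s",
                          "duty_cycle_period_s", "gate_time_s", "per_scan")}
    return OdmrTimeSeries(frequency_grid=grid, counts=counts, meta=extra, **timing)


# ---------------------------------------------------------------------------
# reports

REPORT_SCHEMA: dict[str, Any] = {
    # field name -> (type, required)
    "preset": (str, True),
    "seeds": (dict, True),
    "temperature": (dict, True),  # bin_times_s, dT_C, se_C, reference_C
    "rheology": (dict, True),  # bin_times_s, values, quantity, units
    "alignment": (dict, True),  # bin seconds for both channels, wall-clock span
    "classification": (dict, False),
    "sensitivity": (dict, False),
}

_TEMPERATURE_KEYS = {"bin_times_s", "dT_C", "se_C", "reference_C"}
_RHEOLOGY_KEYS = {"bin_times_s", "values", "quantity", "units"}
_ALIGNMENT_KEYS = {"temperature_bin_s", "rheology_bin_s", "span_s"}


def validate_report(report: dict[str, Any]) -> None:
    """Structural validation of a dual-modality report dictionary."""
    for key, (typ, required) in REPORT_SCHEMA.items():
        if key not in report:
            if required:
                raise FormatError(f"report missing required field {key!r}")
            continue
        if not isinstance(report[key], typ):
            raise FormatError(f"report field {key!r} must be {typ.__name__}")
    for keys, section in ((_TEMPERATURE_KEYS, "temperature"),
                          (_RHEOLOGY_KEYS, "rheology"),
                          (_ALIGNMENT_KEYS, "alignment")):
        missing = keys - set(report[section])
        if missing:
            raise FormatError(f"report section {section!r} missing {sorted(missing)}")
    n_t = len(report["temperature"]["bin_times_s"])
    if n_t != len(report["temperature"]["dT_C"]):
        raise FormatError("temperature trace lengths disagree")
    if len(report["rheology"]["bin_times_s"]) != len(report["rheology"]["values"]):
        raise FormatError("rheology trace lengths disagree")


def write_report(report: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    validate_report(report)
    path.write_text(json.dumps(report, indent=2, default=_json_default))
    return path


def read_report(path: str | Path) -> dict[str, Any]:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")
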