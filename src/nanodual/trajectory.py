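"""Trajectory container for orbital-tracking particle positions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

DEFAULT_SAMPLING_PERIOD = 9.6e-3  # s, one tracking orbit
DEFAULT_NOISE_FLOOR = 1e-4  # um^2, MSD floor of the tracking system
# Isotropic per-axis localization sigma such that the static transverse
# (2-axis) MSD plateau 4*sigma^2 equals the 1e-4 um^2 noise floor.
DEFAULT_LOCALIZATION_SIGMA = 5.0  # nm


@dataclass
class Trajectory:
    """Timestamped 3D particle positions at a fixed sampling period.

    Attributes
    ----------
    times : (N,) float array, seconds, uniformly spaced.
    positions : (N, 3) float array, nm.
    sampling_period : float, s.
    localization_sigma : float, nm per axis of additive localization noise.
    noise_floor : float, um^2; MSD values at or below this are instrument-limited.
    meta : free-form provenance (generator name, parameters, seed).
    """

    times: np.ndarray
    positions: np.ndarray
    sampling_period: float
    localization_sigma: float = 0.0
    noise_floor: float = DEFAULT_NOISE_FLOOR
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.positions.shape != (self.times.size, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{self.times.size} time samples"
            )
        steps = np.diff(self.times)
        if not np.all(steps > 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, self.sampling_period, rtol=1e-6, atol=1e-12):
            raise ValueError("times must be uniform at sampling_period")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def axis_columns(self, axes: tuple[str, ...]) -> np.ndarray:
        """Positions restricted to a subset of axes, shape (N, len(axes))."""
        index = {"x": 0, "y": 1, "z": 2}
        bad = [a for a in axes if a not in index]
        if bad or not axes:
            raise ValueError(f"axes must be a non-empty subset of x,y,z, got {axes}")
        return self.positions[:, [index[a] for a in axes]]
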