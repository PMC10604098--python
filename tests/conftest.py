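import numpy as np
import pytest

from nanodual.synthetic import SpectrumModel, generate_odmr_series, simulate_brownian
from nanodual.trajectory import Trajectory


@pytest.fixture(scope="session")
def spectrum_model() -> SpectrumModel:
    return SpectrumModel()


@pytest.fixture(scope="session")
def brownian_traj() -> Trajectory:
    """Medium-length free Brownian trajectory without localization noise."""
    return simulate_brownian(2e3, 20_000, seed=11, localization_sigma=0.0)


@pytest.fixture(scope="session")
def short_odmr(spectrum_model) -> "object":
    """Ten duty cycles of shot-noise ODMR at constant temperature."""
    return generate_odmr_series(30.0, spectrum_model, duration=2.0, seed=5)


@pytest.fixture()
def straight_line_traj() -> Trajectory:
    """Deterministic ballistic track along x at 500 nm/s."""
    dt = 9.6e-3
    n = 400
    t = np.arange(n) * dt
    pos = np.zeros((n, 3))
    pos[:, 0] = 500.0 * t
    return Trajectory(times=t, positions=pos, sampling_period=dt)
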