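"""MSD, variance estimator, Stokes-Einstein, Mason moduli, PSD forces."""

import numpy as np
import pytest

from nanodual import constants as c
from nanodual.rheometry import (
    ComplexModulus,
    MsdCurve,
    attach_msd_variance,
    compute_msd,
    decompose_forces,
    ensemble_msd,
    estimate_diffusion,
    mason_modulus,
    msd_variance,
    stokes_einstein_radius,
    welch_psd,
)
from nanodual.synthetic import (
    MediumModel,
    glycerol_viscosity,
    simulate_brownian,
    stokes_einstein_diffusion,
)
from nanodual.trajectory import Trajectory


def _traj_from_positions(pos: np.ndarray, dt: float = 9.6e-3) -> Trajectory:
    return Trajectory(times=np.arange(pos.shape[0]) * dt, positions=pos,
                      sampling_period=dt)


class TestComputeMsd:
    def test_single_pair(self):
        pos = np.zeros((2, 3))
        pos[1, 0] = 3.0  # nm
        curve = compute_msd(_traj_from_positions(pos), axes=("x",), max_lag=1)
        assert curve.msd[0] * c.UM2_TO_NM2 == pytest.approx(9.0)

    def test_straight_line_quadratic(self, straight_line_traj):
        curve = compute_msd(straight_line_traj, axes=("x",))
        assert np.allclose(curve.msd * c.UM2_TO_NM2,
                           (500.0 * curve.lags) ** 2, rtol=1e-9)

    def test_fft_path_matches_direct_evaluation(self, brownian_traj):
        curve = compute_msd(brownian_traj, max_lag=20)
        pos = brownian_traj.positions[:, :2]
        for tau in (1, 7, 20):
            direct = np.mean(np.sum((pos[tau:] - pos[:-tau]) ** 2, axis=1))
            assert curve.msd[tau - 1] * c.UM2_TO_NM2 == pytest.approx(direct, rel=1e-9)

    def test_rotation_invariance_transverse(self, brownian_traj):
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        rotated = _traj_from_positions(brownian_traj.positions @ rot.T)
        a = compute_msd(brownian_traj, max_lag=30)
        b = compute_msd(rotated, max_lag=30)
        assert np.allclose(a.msd, b.msd, rtol=1e-9)

    def test_ensemble_is_pair_count_weighted_average(self):
        trajs = [simulate_brownian(2e3, n, seed=s, localization_sigma=0.0)
                 for s, n in ((1, 600), (2, 1000))]
        pooled = ensemble_msd(trajs, max_lag=50)
        parts = [compute_msd(t, max_lag=50) for t in trajs]
        manual = (
            parts[0].msd * parts[0].n_pairs[:50] + parts[1].msd * parts[1].n_pairs[:50]
        ) / (parts[0].n_pairs[:50] + parts[1].n_pairs[:50])
        assert np.allclose(pooled.msd, manual, rtol=1e-12)

    def test_empty_axis_set_rejected(self, brownian_traj):
        with pytest.raises(ValueError):
            compute_msd(brownian_traj, axes=())


class TestMsdVariance:
    def test_deterministic_trajectory_has_near_zero_variance(self, straight_line_traj):
        var, ok = msd_variance(straight_line_traj, 5, axes=("x",))
        curve = compute_msd(straight_line_traj, axes=("x",))
        assert ok
        assert var < 1e-12 * curve.msd[4] ** 2

    def test_3d_variance_is_sum_of_axes(self, brownian_traj):
        v3, _ = msd_variance(brownian_traj, 8, axes=("x", "y", "z"))
        parts = [msd_variance(brownian_traj, 8, axes=(a,))[0] for a in "xyz"]
        assert v3 == pytest.approx(sum(parts), rel=1e-12)

    @pytest.mark.parametrize("tau", [2, 5, 10])
    def test_matches_brute_force_ensemble(self, tau):
        # mean estimator over trajectories vs true spread of the time average
        n, reps = 1000, 300
        ta_msd, estimates = [], []
        for s in range(reps):
            tr = simulate_brownian(2e3, n, seed=5000 + s, localization_sigma=0.0)
            x = tr.positions[:, 0]
            xi = x[tau:] - x[:-tau]
            ta_msd.append(np.mean(xi**2))
            estimates.append(msd_variance(tr, tau, axes=("x",))[0])
        brute = np.var(ta_msd) * c.NM2_TO_UM2**2
        ratio = np.mean(estimates) / brute
        assert 0.8 < ratio < 1.25

    def test_out_of_regime_flagged(self, brownian_traj):
        with pytest.warns(UserWarning, match="regime"):
            _, ok = msd_variance(brownian_traj, len(brownian_traj) // 3)
        assert not ok

    def test_attach_fills_requested_lags(self, brownian_traj):
        curve = compute_msd(brownian_traj, max_lag=100)
        attach_msd_variance(brownian_traj, curve, lags_steps=np.array([2, 10]))
        assert np.isfinite(curve.variance[[1, 9]]).all()
        assert np.isnan(curve.variance[4])


class TestDiffusionEstimate:
    def test_exact_curve_inverts_to_D(self):
        D = 3e3
        tau = np.arange(1, 200) * 9.6e-3
        curve = MsdCurve(lags=tau, msd=4 * D * tau * c.NM2_TO_UM2,
                         n_pairs=np.full(tau.size, 1000), axes_used=("x", "y"))
        est = estimate_diffusion(curve, lag=float(tau[-1]))
        assert est.D == pytest.approx(D, rel=1e-9)
        fit = estimate_diffusion(curve, method="linear_fit", lag=float(tau[-1]))
        assert fit.D == pytest.approx(D, rel=1e-9)

    def test_recovery_at_one_second(self):
        D = 2e3
        trajs = [simulate_brownian(D, 40_000, seed=s, localization_sigma=0.0)
                 for s in range(4)]
        curve = ensemble_msd(trajs, max_lag=110)
        est = estimate_diffusion(curve, lag=1.0)
        assert est.D == pytest.approx(D, rel=0.1)

    def test_noise_floor_marks_unreliable(self):
        tau = np.arange(1, 50) * 9.6e-3
        curve = MsdCurve(lags=tau, msd=np.full(tau.size, 5e-5),
                         n_pairs=np.full(tau.size, 1000), axes_used=("x", "y"))
        est = estimate_diffusion(curve, lag=float(tau[10]))
        assert est.unreliable

    def test_ci_shrinks_with_trajectory_length(self):
        spreads = []
        for n in (2_000, 8_000):
            estimates = [
                estimate_diffusion(
                    compute_msd(simulate_brownian(2e3, n, seed=s,
                                                  localization_sigma=0.0),
                                max_lag=20),
                    lag=20 * 9.6e-3).D
                for s in range(40)
            ]
            spreads.append(np.std(estimates))
        # error in D scales like 1/sqrt(N): 4x data -> ~2x tighter
        assert spreads[1] == pytest.approx(spreads[0] / 2.0, rel=0.5)


class TestStokesEinstein:
    def test_noiseless_round_trip(self):
        medium = MediumModel(particle_radius=25.0)
        temps = np.linspace(22.0, 39.0, 6)
        d_series = {t: stokes_einstein_diffusion(t, medium) for t in temps}
        r, se = stokes_einstein_radius(d_series, medium)
        assert r == pytest.approx(25.0, rel=1e-9)

    def test_single_point_direct_inversion(self):
        medium = MediumModel(particle_radius=30.0)
        d_series = {30.0: stokes_einstein_diffusion(30.0, medium)}
        r, _ = stokes_einstein_radius(d_series, medium)
        assert r == pytest.approx(30.0, rel=1e-9)

    def test_noisy_recovery_within_one_nm(self):
        # 5% noise on D at 6 temperatures, many repeats: r to +-1 nm
        medium = MediumModel(particle_radius=25.0)
        temps = np.linspace(22.0, 39.0, 6)
        truth = np.array([stokes_einstein_diffusion(t, medium) for t in temps])
        rng = np.random.default_rng(3)
        fitted = []
        for _ in range(100):
            noisy = truth * (1.0 + 0.05 * rng.standard_normal(truth.size))
            fitted.append(stokes_einstein_radius(dict(zip(temps, noisy)), medium)[0])
        fitted = np.asarray(fitted)
        assert abs(fitted.mean() - 25.0) < 1.0
        assert fitted.std() < 1.0


class TestMasonModulus:
    @staticmethod
    def _viscous_curve(D: float, n: int = 4000) -> MsdCurve:
        tau = np.arange(1, n) * 9.6e-3
        return MsdCurve(lags=tau, msd=4 * D * tau * c.NM2_TO_UM2,
                        n_pairs=np.full(tau.size, 10_000), axes_used=("x", "y"))

    def test_viscous_limit_recovers_viscosity_exactly(self):
        medium = MediumModel()
        T = c.celsius_to_kelvin(30.0)
        eta = glycerol_viscosity(30.0, medium)
        D = stokes_einstein_diffusion(30.0, medium)
        mod = mason_modulus(self._viscous_curve(D), T=T,
                            radius=medium.particle_radius)
        eta_rec = mod.G_double_prime / (2 * np.pi * mod.f)
        assert np.allclose(eta_rec, eta, rtol=1e-3)
        assert np.allclose(mod.loss_tangent, np.pi / 2, atol=1e-3)
        assert np.all(np.abs(mod.G_prime) < 1e-2 * mod.G_double_prime)

    def test_simulated_viscous_round_trip_within_5_percent(self):
        medium = MediumModel()
        T_c = 30.0
        eta = glycerol_viscosity(T_c, medium)
        D = stokes_einstein_diffusion(T_c, medium)
        trajs = [simulate_brownian(D, 100_000, seed=s, localization_sigma=0.0)
                 for s in range(3)]
        curve = ensemble_msd(trajs)
        mod = mason_modulus(curve, T=c.celsius_to_kelvin(T_c),
                            radius=medium.particle_radius)
        mid = (mod.f > 0.05) & (mod.f < 2.0)
        eta_rec = np.median((mod.G_double_prime / (2 * np.pi * mod.f))[mid])
        assert eta_rec == pytest.approx(eta, rel=0.05)
        assert np.median(mod.loss_tangent[mid]) == pytest.approx(np.pi / 2, rel=0.05)

    def test_flat_msd_is_purely_elastic(self):
        tau = np.geomspace(0.01, 10.0, 100)
        curve = MsdCurve(lags=tau, msd=np.full(tau.size, 3e-4),
                         n_pairs=np.full(tau.size, 1000), axes_used=("x", "y"))
        mod = mason_modulus(curve, T=300.0, radius=25.0)
        assert np.allclose(mod.loss_tangent, 0.0, atol=1e-6)
        assert np.allclose(mod.G_double_prime, 0.0, atol=1e-9 * mod.G_abs.max())

    def test_gabs_identity(self):
        mod = mason_modulus(self._viscous_curve(2e3), T=300.0, radius=25.0)
        assert np.allclose(mod.G_abs**2,
                           mod.G_prime**2 + mod.G_double_prime**2, rtol=1e-12)


class TestWelchPsd:
    def test_sinusoid_peaks_at_its_frequency(self):
        dt = 9.6e-3
        t = np.arange(6000) * dt
        pos = np.zeros((t.size, 3))
        pos[:, 0] = 100.0 * np.sin(2 * np.pi * 40.0 * t)
        psd = welch_psd(_traj_from_positions(pos), window=28.8)
        assert psd.f[np.argmax(psd.psd_total)] == pytest.approx(40.0, abs=0.2)

    def test_parseval_normalization(self, brownian_traj):
        psd = welch_psd(brownian_traj, window=28.8, axes=("x",))
        x = brownian_traj.positions[:3000, 0] * 1e-3  # one segment, um
        var = np.var(x - x.mean())
        total = np.sum(psd.psd_per_axis["x"]) * (psd.f[1] - psd.f[0])
        # Welch-averaged spectrum integrates to the segment variance scale
        assert total == pytest.approx(var, rel=0.8)

    def test_brownian_spectrum_slope_minus_2(self, brownian_traj):
        psd = welch_psd(brownian_traj, window=28.8)
        band = (psd.f > 0.5) & (psd.f < 10.0)
        slope = np.polyfit(np.log(psd.f[band]), np.log(psd.psd_total[band]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.1)

    def test_window_longer_than_trajectory_rejected(self):
        short = simulate_brownian(1e3, 100, seed=0)
        with pytest.raises(ValueError, match="window"):
            welch_psd(short, window=28.8)


class TestForceDecomposition:
    @staticmethod
    def _setup(traj):
        T = c.celsius_to_kelvin(30.0)
        psd = welch_psd(traj, window=28.8)
        msd = compute_msd(traj)
        mod = mason_modulus(msd, T=T, radius=25.0)
        return psd, mod, T

    def test_equilibrium_brownian_has_no_active_force(self, brownian_traj):
        psd, mod, T = self._setup(brownian_traj)
        dec = decompose_forces(psd, mod, T=T, radius=25.0, f_range=(0.5, 10.0))
        thermal_force = np.abs(dec.spring_constant) ** 2 \
            * dec.thermal_psd_bound * c.UM2_TO_M2
        assert np.mean(dec.external_force_psd / thermal_force) < 0.25

    def test_injected_kicks_raise_external_force(self):
        rng = np.random.default_rng(8)
        base = simulate_brownian(2e3, 20_000, seed=11, localization_sigma=0.0)
        levels = []
        for kick in (0.0, 40.0, 80.0):  # nm rms extra jitter
            pos = base.positions.copy()
            pos[:, :2] += rng.normal(scale=max(kick, 1e-12), size=(pos.shape[0], 2))
            traj = _traj_from_positions(pos)
            psd, mod, T = self._setup(base)
            dec = decompose_forces(welch_psd(traj, window=28.8), mod, T=T,
                                   radius=25.0, f_range=(5.0, 20.0))
            levels.append(np.median(dec.external_force_psd))
        assert levels[0] < levels[1] < levels[2]

    def test_stiffer_spring_quadruples_total_force(self):
        f = np.geomspace(0.5, 10, 20)
        base_mod = ComplexModulus(
            f=f, G_prime=np.zeros_like(f),
            G_double_prime=2 * np.pi * f * 0.3,
            G_abs=2 * np.pi * f * 0.3,
            loss_tangent=np.full_like(f, np.pi / 2),
            alpha_local=np.ones_like(f),
        )
        doubled = ComplexModulus(
            f=f, G_prime=np.zeros_like(f),
            G_double_prime=2 * base_mod.G_double_prime,
            G_abs=2 * base_mod.G_abs,
            loss_tangent=base_mod.loss_tangent,
            alpha_local=base_mod.alpha_local,
        )
        traj = simulate_brownian(2e3, 20_000, seed=4, localization_sigma=0.0)
        psd = welch_psd(traj, window=28.8)
        T = 300.0
        a = decompose_forces(psd, base_mod, T=T, radius=25.0, f_range=(1, 8))
        b = decompose_forces(psd, doubled, T=T, radius=25.0, f_range=(1, 8))
        total_a = np.abs(a.spring_constant) ** 2 * a.f  # |K|^2 <x^2> ~ total force
        total_b = np.abs(b.spring_constant) ** 2 * b.f
        assert np.allclose(total_b, 4 * total_a, rtol=1e-9)
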