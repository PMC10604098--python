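# nanodual

Dual-modality nanodiamond sensing analysis: **ODMR nanothermometry** and
**single-particle-tracking nanorheometry**, exercised end to end on
synthetic data emulating orbital-tracking experiments on
nitrogen-vacancy (NV) nanodiamonds.

## Who this is for

Nanodiamonds carrying NV-center ensembles can report the local
temperature (the spin resonance frequency shifts with temperature) and,
tracked in real time, the local mechanical properties of their
surroundings (their stochastic motion encodes the medium's
viscoelasticity and any active forces).  This package implements the
full analysis chain for such dual-modality experiments — and, because no
public datasets of this kind exist, a first-class synthetic-data module
that emulates every input: 3D trajectories at the 9.6 ms orbital-tracking
period, streams of 200-point ODMR photon-count spectra with the
160/200 ms duty cycle, RTD resistance traces, and the double-plane
orbital tracking feedback loop itself.

## The models at the core

**Thermometry.** The NV ODMR dip center moves with temperature at
κ = −60.0 kHz/°C.  The whole photon-count record defines a
piecewise-linear interpolation template; each 400 ms bin is fit against
the template evaluated at shifted frequencies (free amplitude and offset
absorb photoluminescence drift), giving δf and hence ΔT = δf/κ.
Precision is characterized by the overlapping Allan deviation σ_A(τ):
in the white-noise region σ_A(τ)·√τ is the sensitivity in K/√Hz, which
is benchmarked against the shot-noise Cramér–Rao bound computed from the
Poisson Fisher information I = Σᵢ (∂λᵢ/∂f₀)²/λᵢ of the same spectrum
model and photon budget.

**Rheometry.** From the time-averaged transverse MSD,
MSD(τ) = (1/K)Σᵢ|r(i+τ)−r(i)|² with K = N−τ, the package estimates
diffusion coefficients (MSD = 4Dτ for free Brownian motion),
hydrodynamic radii through the Stokes–Einstein relation
D = k_BT/(6πη(T)r), and frequency-dependent viscoelastic moduli through
Mason's power-law form of the generalized Stokes–Einstein relation,

    |G*(ω)| = 2 k_B T / (3π r · MSD(1/ω) · Γ[1+α(ω)]),   δ = πα/2,

with α the local log-log slope of the MSD.  The MSD's inherent
stochastic variance is estimated from the autocovariance of overlapping
displacement pairs, and a 10⁻⁴ μm² instrument noise floor is enforced.
Position power spectra (Welch, 28.8 s windows) are decomposed via
Hooke's law, ⟨x²(ω)⟩ = (⟨ξ²(ω)⟩ + ⟨F_ext²(ω)⟩)/|K(ω)|² with
K(ω) = 6πr·G*(ω), into the thermal bound and an active-force excess.

**Motion classification.** Sliding-window directionality ratios
γ = displacement/path-length are compared against a Monte-Carlo Brownian
null; persistent above-threshold runs become "directed" segments, and
per-segment anomalous exponents α (MSD ∝ τ^α) are summarized by normal
fits with sub/diffusive/superdiffusive fractions.

## Worked example

```python
import numpy as np
from nanodual import (SpectrumModel, ThermometryCalibration, MediumModel,
    generate_odmr_series, build_template, fit_frequency_shifts,
    shift_to_temperature, sensitivity_report, simulate_brownian,
    compute_msd, attach_msd_variance, estimate_diffusion, mason_modulus,
    stokes_einstein_diffusion, glycerol_viscosity)

# --- thermometry: 10 minutes of shot-noise-limited ODMR at 30 C
model, cal = SpectrumModel(), ThermometryCalibration()
series = generate_odmr_series(30.0, model, duration=600.0, seed=1)
template = build_template(series)
shifts = fit_frequency_shifts(series, template)
dT = np.asarray(shift_to_temperature(shifts.shifts, cal))
rep = sensitivity_report(dT, 0.4, model, series, cal)

# --- rheometry: a nanodiamond diffusing in glycerol at 30 C
medium = MediumModel()
D_true = stokes_einstein_diffusion(30.0, medium)   # 21930 nm^2/s
traj = simulate_brownian(D_true, 100_000, seed=2, localization_sigma=0.0)
msd = compute_msd(traj)
attach_msd_variance(traj, msd, lags_steps=np.array([104]))
est = estimate_diffusion(msd, lag=1.0)
mod = mason_modulus(msd, T=303.15, radius=25.0)
```

prints (via the obvious format strings):

```
Allan sensitivity:     2.53 K/sqrt(Hz)
Cramer-Rao bound:      2.34 K/sqrt(Hz)
relative excess:       8.3 %
D (input):             21930 nm^2/s
D (MSD at 1 s):        21766 +- 566 nm^2/s
eta (input):           0.405 Pa s
eta (Mason G''/omega): 0.407 Pa s
loss tangent delta:    1.554 rad (pi/2 = 1.571)
```

The measured sensitivity sits within 10% of the shot-noise bound — the
interpolation fit is nearly efficient.  The recovered diffusion
coefficient matches the programmed one within its confidence interval,
the Mason inversion returns the generator's viscosity, and the loss
tangent sits at π/2 as it must for a purely viscous medium.

A command-line interface mirrors the library
(`nanodual simulate ... | thermometry | rheometry | classify | run`);
`nanodual run --preset glycerol --duration 120 --seed 1 --outdir out/`
produces the full set of stage artifacts plus a time-aligned
dual-modality report JSON.

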