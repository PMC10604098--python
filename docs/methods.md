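# Methods

This note records the models behind each stage, the defaults that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic data does and does not emulate.

## Synthetic data

The generators define the study conditions; everything downstream is
measured, never assumed.

**Trajectories.** Positions are sampled at the orbital-tracking period
(9.6 ms default).  Free Brownian motion draws per-axis increments
N(0, 2D·dt).  Anomalous diffusion uses fractional Gaussian noise with
Hurst index α/2, generated exactly by circulant embedding
(Davies–Harte); the per-axis ensemble MSD is 2·scale·τ^α so that α = 1,
scale = D reproduces Brownian statistics.  Directed motion adds a
ballistic drift v·t to a Brownian component; with v = 0 it is
bit-identical to the Brownian generator at the same seed.  Localization
noise is additive isotropic Gaussian per sample; its default σ = 5 nm
per axis makes the static transverse MSD plateau (4σ²) equal the
10⁻⁴ μm² noise floor of the tracking instrument, which is carried on
every trajectory and respected by all MSD consumers.

**ODMR streams.** A 200-point frequency grid spans 30 MHz around
2870 MHz.  The ensemble-NV lineshape is two Lorentzian dips (FWHM 8 MHz)
split symmetrically by 6 MHz, normalized so the deepest point sits at
1 − contrast (contrast 0.10); a single broad dip is configurable.  The
lineshape parameters are a modeling choice — only the timing, photon
budget and κ are constrained by the emulated instrument.  Timing: 10 μs
gate per frequency point, 2 ms per scan, 80 scans per 160 ms window,
200 ms duty cycle with a 40 ms dead time (heater window) in which no
counts are collected.  Per-gate counts are Poisson with mean
rate·gate·profile(f; f₀ + κΔT); at the default 1 Mcps (two detectors
summed) each APD expects 5 counts per gate.  Counts are stored summed
per window — a sum of Poisson variables is Poisson, so the statistics
are exact while a 30-minute record stays at 9000×200 integers; per-scan
storage is available for short runs.

**Temperature-to-viscosity coupling.** Glycerol viscosity is linear in
temperature with dη/dT = −0.0208 Pa·s/°C, η(35 °C) = 0.301 Pa·s,
supported over 21–40 °C (extrapolation warns).  The slope sign is
chosen so the medium thins on heating, as any real liquid does; η₀, μ
and T₀ are configurable because published parameterizations of
glycerol's η(T) differ.

**Orbital tracker.** The simulator orbits the beam (radius 50 nm,
64 points per orbit) around the last inferred position while two
collection planes offset ±50 nm axially record Poisson counts from a
Gaussian point-spread function (transverse 1/e² radius 250 nm, axial
half-length 600 nm, emitter rate split evenly between planes).  The
transverse correction inverts the first Fourier harmonic of counts
around the orbit, d̂ = (w²/2R)·(Σn·e^(iθ))/Σn, the axial correction the
log-imbalance of the planes, ẑ = (w_z²/8s)·ln(N_top/N_bot), each scaled
by a proportional gain (defaults 1.0 transverse, 0.5 axial).  This
feedback law is a clean-room design with the contracted properties —
unbiased fixed point, shot-noise-limited error (a few nm per 9.6 ms
update at 1 Mcps), bounded error for gains in (0, 1] — rather than an
emulation of any particular firmware; the real instrument's 6 μs
compute path and galvo mapping are out of scope.  A particle farther
than 3 PSF radii from the tracker is flagged lost.

## Thermometry

The template is the unit-mean average spectrum of the whole record,
evaluated anywhere by piecewise-linear interpolation.  Each 400 ms bin
(two duty cycles) is fit by minimizing Σ(y − a·T(f − δf) − b)² over
δf with free amplitude a and offset b: raw photoluminescence drifts in
cells, and for a symmetric lineshape on a symmetric grid these nuisance
directions are orthogonal to the shift, so they cost essentially no
precision.  The search runs on a grid of one tenth of the frequency
spacing (15 kHz) followed by a three-point parabolic refinement
(tolerance well under 1 kHz on noiseless data); shifts beyond a quarter
of the grid span are flagged out of range.  Standard errors come from
the local curvature of the residual sum of squares.  Consecutive shifts
are averaged in non-overlapping blocks of n_f = 25 (10 s per reported
point; the averaging count is a free choice and configurable), each
block carrying the standard error of its members.

Sensitivity uses the overlapping Allan deviation at octave-spaced
averaging times.  The white-noise region is found by sliding four-point
log-log fits accepting slope −0.5 ± 0.1; over the accepted points,
σ_A(τ)·√τ is averaged weighted by the number of independent two-sample
differences at each τ (≈ N/m), since large-τ deviations carry few
degrees of freedom and would otherwise dominate the scatter of the
estimate.  The Cramér–Rao benchmark is the Poisson Fisher information
of the spectrum model summed over the grid, accumulated over 80 scans
per 200 ms duty cycle (the 40 ms dead time thus degrades sensitivity by
√(0.2/0.16) relative to continuous acquisition), converted to
temperature via |κ|.  On 30-minute simulated records the Allan
sensitivity lands 3–6% above the bound: the piecewise-linear template
and unweighted least squares are nearly, not exactly, efficient.

The RTD channel is the standard linear metal-resistance model
T = T₀ + (R/R₀ − 1)/η_RTD with η_RTD = 2.44×10⁻³/°C, the exact inverse
of its generator.

## Rheometry

MSD is computed by FFT (O(N log N)) for all lags up to N/4 — beyond
that too few pairs remain for the variance estimator's regime.  The
variance of the time average at lag τ accounts for the correlation of
overlapping displacement pairs: with ĉ(d) the empirical autocovariance
of the displacement sequence and the Gaussian fourth-moment identity
Cov(ξᵢ², ξⱼ²) = 2c(i−j)²,

    Var[MSD(τ)] = (2/K²) Σ_{|d|<τ} (K−|d|) ĉ(d)²,

summed per axis (spatial directions are uncorrelated, so the 3D
variance is the sum of per-axis variances).  It is validated against a
500-trajectory brute-force ensemble (ratio within [0.8, 1.25] at
τ = 2, 5, 10 steps) and declared valid only for τ ≤ K/10, K ≥ 100; the
reported MSD error falls back to the noise floor whenever the
statistical error or the MSD itself is below 10⁻⁴ μm².

Diffusion coefficients use the MSD at a 1 s lag (D = MSD/2d·τ, d axes)
or a variance-weighted linear fit through the origin.  The hydrodynamic
radius is the single free parameter of D(T) = k_BT/(6πη(T)r); the model
is linear in 1/r, so the weighted least-squares solution is closed-form
and positive whenever the D estimates are.

Mason's GSER is evaluated at angular frequency ω = 1/τ (reported as
f = ω/2π), with the prefactor for the transverse two-axis MSD:
|G*| = 2k_BT/(3πr·MSD·Γ[1+α]).  This normalization is fixed by the
viscous-limit oracle — an exactly linear MSD = 4Dτ with
D = k_BT/(6πηr) returns G″(f) = 2πfη identically — because the
dimensional prefactor is the one genuinely open choice in local
power-law microrheology.  The local exponent α(τ) is the derivative of
a quadratic fit to ln MSD over a ±3-point window on a log-spaced lag
grid (16 points per decade), clipped to [0, 2] with a warning; lags at
the noise floor are excluded.  δ = πα/2, G′ = |G*|cos δ,
G″ = |G*|sin δ; MSD errors propagate at fixed α.

PSDs use Welch's method with 28.8 s segments (one-sided, density
normalization), summed over the two transverse axes, with the readout
value taken at the bin nearest 40 Hz.  The force decomposition treats
the medium as a complex spring K(ω) = 6πr·G*(ω); the
fluctuation-dissipation theorem sets the thermal position PSD per axis
at 4k_BT·K″/(ω|K|²), and the active-force power is
⟨F_ext²⟩ = |K|²·(S_meas − S_th), clipped at zero with the clipped bins
flagged.  |G*| and δ are interpolated log-log onto the PSD grid,
extrapolating the local power law where the MSD-derived band
(f ≲ 1/(4π·dt)) does not reach the PSD band; equilibrium checks are run
within the overlapping band, where discrete-sampling distortion of the
1/f² spectrum is also negligible.

## Motion classification

The directionality ratio γ = |r(end)−r(start)| / Σ|steps| is computed
in the transverse plane.  The null threshold is the 99th percentile of
γ over 10⁴ simulated Brownian windows matched in D, window length
(50 steps ≈ 0.48 s) and localization noise — for noise-free Brownian
motion γ is scale-invariant, but the matching matters once a noise
plateau exists.  Sliding-window flags are merged when separated by
fewer than 3 windows and kept only when at least 10 windows long,
suppressing single-window flickers; these constants are configurable
and deliberately conservative (isolated short excursions of a Brownian
path above the 99th percentile survive at a low rate, bounded in the
tests).  Per-segment α uses lags from 2 samples to a quarter of the
segment length.  Exponent fits subsample the lag grid logarithmically
(16 points per decade) before the ln-ln regression: with all linear
lags, half the points fall in the last octave where the time-averaged
MSD is noisiest and log-transformed fluctuations bias the slope
downward; log spacing keeps the ensemble-mean bias below 0.05 for
α ∈ {0.3, 1.0, 1.65} at 10⁴-step trajectories.  The α summary reports
a maximum-likelihood normal fit and class fractions with a ±0.1
"diffusive" band around α = 1 (the band is presentation only; the
classification boundary is α = 1).

## Pipeline and reporting

Both data streams share one wall clock and one temperature program but
independent seeds; perturbing one stream provably leaves the other's
trace unchanged.  Presets: `glycerol` (Brownian with D(T) from
Stokes–Einstein), `gcx_like` (subdiffusive fBm, α = 0.5, whose MSD
amplitude grows with temperature so |G*| falls when hot), `cell_like`
(Brownian with a directed interval in the middle third), and
`nocodazole_like` (α = 0.3 fBm, the motor-suppressed weak-gel regime).
Temperature bins are n_f × 400 ms, rheology bins 30 s, both left-closed
intervals labeled by their left edge.  Reports serialize to JSON and
are validated structurally on both write and read; every artifact
records its seeds, and identical configurations reproduce byte-identical
outputs.

## Problem sizes

Defaults used by the acceptance script and the heavier tests: 10 × 10⁵
steps for the MSD proportionality constant, 100 × 10⁴ steps for
exponent recovery, a 30-minute ODMR record (9000 windows, 4500 bins)
for the sensitivity benchmark, 500 trajectories × 10³ steps for the
variance-estimator oracle, and 3 × 10⁵ steps for the viscous GSER round
trip.  All complete in seconds on one CPU.

## Known limitations

The synthetic data is idealized: Gaussian displacement statistics,
stationary media within each temperature plateau, no photobleaching,
background fluorescence, magnetic-field or strain shifts of the NV
resonance, no tracker-trajectory coupling (analysis trajectories are
generated directly rather than passed through the tracker simulator),
and localization noise that is white rather than feedback-correlated.
Passing tests therefore demonstrate the correctness of the estimators
under their stated assumptions, not robustness to every systematic a
real instrument exhibits.  The Mason inversion assumes a locally
power-law MSD and degrades near the ends of the lag range; the force
decomposition inherits the GSER's assumption of a linear
force-displacement relation.
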