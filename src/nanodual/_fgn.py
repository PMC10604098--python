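"""Fractional Gaussian noise via circulant embedding (Davies-Harte).

Generates exact stationary Gaussian sequences with the fractional-Gaussian-
noise autocovariance for Hurst index H in (0, 1).  Cumulative sums of the
output are fractional Brownian motion, the standard model for anomalous
diffusion with MSD proportional to t^(2H).
"""

from __future__ import annotations

import numpy as np


def fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    """Autocovariance gamma(0..n-1) of unit-variance fGn with Hurst index H."""
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def sample_fgn(
    n: int,
    hurst: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw `size` independent unit-variance fGn sequences of length `n`.

    Uses the circulant embedding of the covariance into a 2(n-1) circulant
    matrix whose eigenvalues are obtained by FFT; the embedding is
    non-negative definite for fGn across the full Hurst range.  Tiny negative
    eigenvalues from roundoff are clipped; a genuinely failed embedding
    raises instead of silently producing a wrong covariance.

    Returns array of shape (size, n).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst index must be in (0, 1), got {hurst}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return rng.standard_normal((size, 1))

    gamma = fgn_autocovariance(n, hurst)
    # first row of the circulant embedding: gamma_0 .. gamma_{n-1}, gamma_{n-2} .. gamma_1
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size  # 2(n-1)
    eigs = np.fft.rfft(row).real
    floor = -1e-8 * eigs.max()
    if eigs.min() < floor:
        raise RuntimeError(
            "circulant embedding produced significantly negative eigenvalues; "
            f"min eigenvalue {eigs.min():.3e}"
        )
    eigs = np.clip(eigs, 0.0, None)

    # complex Gaussian spectrum with Hermitian symmetry handled by irfft
    n_freq = eigs.size  # m//2 + 1
    zr = rng.standard_normal((size, n_freq))
    zi = rng.standard_normal((size, n_freq))
    # DC and Nyquist components are real with doubled variance
    zi[:, 0] = 0.0
    zr[:, 0] *= np.sqrt(2.0)
    if m % 2 == 0:
        zi[:, -1] = 0.0
        zr[:, -1] *= np.sqrt(2.0)
    spectrum = (zr + 1j * zi) * np.sqrt(eigs / (2.0 * m))
    out = np.fft.irfft(spectrum, n=m, axis=1) * m
    return out[:, :n]
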