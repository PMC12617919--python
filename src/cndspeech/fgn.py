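"""Fractional Gaussian noise (fGn) by circulant embedding.

fGn is the stationary increment process of fractional Brownian motion;
with Hurst exponent H > 0.5 it shows the long-range-correlated
spontaneous-rate fluctuations observed in auditory-nerve fibers. The
sampler embeds the Toeplitz autocovariance in a circulant matrix
(Dietrich-Newsam construction), which is exact whenever the circulant
eigenvalues are non-negative (true for all H in (0, 1) at the sizes used
here; tiny negative eigenvalues from roundoff are clipped).
"""

from __future__ import annotations

import numpy as np


def fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    """Autocovariance of unit-variance fGn at lags 0..n-1."""
    k = np.arange(n, dtype=np.float64)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def sample_fgn(n_samples: int, hurst: float = 0.9, size: int = 1,
               rng: np.random.Generator | None = None,
               dtype=np.float64) -> np.ndarray:
    """Draw ``size`` independent unit-variance fGn series of length
    ``n_samples``; returns an array of shape (size, n_samples)."""
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {hurst}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if n_samples == 1:
        return rng.standard_normal((size, 1), dtype=dtype)
    # embed a (possibly longer) series so the circulant length is an
    # FFT-friendly size; the leading n_samples are distributed identically
    from scipy.fft import fft, next_fast_len

    n_gen = next_fast_len(2 * (n_samples - 1)) // 2 + 1
    gamma = fgn_autocovariance(n_gen, hurst)
    c = np.concatenate([gamma, gamma[-2:0:-1]])
    m = len(c)
    lam = np.maximum(fft(c).real, 0.0)  # clip roundoff negatives
    # interleaved normal draw: a size-k batch is a prefix of a larger batch
    # from the same generator state
    dtype = np.dtype(dtype)
    cplx = np.complex64 if dtype == np.float32 else np.complex128
    z = rng.standard_normal((size, m, 2), dtype=dtype).view(cplx)[..., 0]
    x = fft(np.sqrt(lam / m).astype(dtype) * z, axis=-1)
    # E[z z*] = 2, and the real part keeps half of it: covariance is exact
    return np.ascontiguousarray(x.real[:, :n_samples])
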