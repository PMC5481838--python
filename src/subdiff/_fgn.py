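"""Exact synthesis of fractional Gaussian noise.

Fractional Brownian motion B_H has stationary Gaussian increments (fractional
Gaussian noise, fGn) with autocovariance

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}),

so a path with MSD exponent alpha is obtained by cumulatively summing fGn with
Hurst index H = alpha / 2.  The default synthesis is circulant embedding
(Davies-Harte), which is exact and O(n log n); short paths fall back to a
Cholesky factor of the increment covariance, which is exact for any valid H.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fgn_autocovariance", "sample_fgn"]


def fgn_autocovariance(hurst: float, n: int) -> np.ndarray:
    """Autocovariance gamma(0..n-1) of unit-variance fGn with Hurst index H."""
    k = np.arange(n, dtype=float)
    return 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))


def _circulant_eigenvalues(hurst: float, n: int) -> np.ndarray | None:
    gamma = fgn_autocovariance(hurst, n + 1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-9 * max(1.0, lam.max()):
        return None  # embedding not nonneg-definite; caller falls back
    return np.clip(lam, 0.0, None)


def _sample_davies_harte(rng: np.random.Generator, lam: np.ndarray, n: int,
                         n_series: int) -> np.ndarray:
    m = lam.size  # 2n
    out = np.empty((n_series, n))
    # batch to bound the memory of the complex work array
    batch = max(1, int(4e7 // m))
    scale = np.sqrt(lam / (2 * m))
    for s in range(0, n_series, batch):
        b = min(batch, n_series - s)
        w = rng.standard_normal((b, m)) + 1j * rng.standard_normal((b, m))
        z = np.fft.fft(w * scale, axis=1)
        out[s:s + b] = z[:, :n].real * np.sqrt(2.0)
    return out


def sample_fgn(rng: np.random.Generator, hurst: float, n: int,
               n_series: int = 1) -> np.ndarray:
    """Draw `n_series` independent fGn series of length `n`, unit variance.

    Parameters
    ----------
    rng : seeded generator; identical state gives identical output.
    hurst : Hurst index in (0, 1).  H = 0.5 reduces to white noise.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if hurst == 0.5:
        return rng.standard_normal((n_series, n))
    if n >= 16:
        lam = _circulant_eigenvalues(hurst, n)
        if lam is not None:
            return _sample_davies_harte(rng, lam, n, n_series)
    # Cholesky fallback: exact for short series
    gamma = fgn_autocovariance(hurst, n)
    cov = gamma[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return rng.standard_normal((n_series, n)) @ chol.T
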