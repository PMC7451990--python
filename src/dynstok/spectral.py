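"""Frequency-domain transforms of tvMVAR coefficients.

From the time-varying coefficient matrices ``A_{k,t}`` the spectral matrix

    Abar(f, t) = I - sum_{k=1..p} A_{k,t} exp(-i 2 pi f k / fs)

is formed on a frequency grid (Hz, up to Nyquist).  Squared row-normalized
partial directed coherence (PDC) measures the direct influence of channel j
on channel l at (f, t):

    pdc[l, j] = |Abar_lj|^2 / sum_m |Abar_lm|^2

so every row sums to one over sources.  The parametric power spectral density
uses the transfer function ``B = Abar^-1`` and a time-invariant innovation
covariance ``Sigma``: ``PSD(f, t) = B Sigma B*``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TvmvarEstimate

_ROW_SUM_TOL = 1e-9


@dataclass
class SpectralConnectivity:
    """PDC or PSD tensor over (target, source, frequency, time).

    For ``kind="pdc"`` values lie in [0, 1] and every row sums to 1 over
    sources; for ``kind="psd"`` values hold the complex cross-spectral matrix
    whose diagonal is the real, nonnegative per-channel power spectrum.
    """

    values: np.ndarray
    freqs: np.ndarray
    fs: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("pdc", "psd"):
            raise ValueError("kind must be 'pdc' or 'psd'")
        if self.values.ndim != 4 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must have shape (d, d, F, T)")
        if self.values.shape[2] != self.freqs.size:
            raise ValueError("frequency axis mismatch")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[3]

    def diagonal_spectra(self) -> np.ndarray:
        """Per-channel real spectra, shape (d, F, T)."""
        d = self.n_channels
        return np.real(self.values[np.arange(d), np.arange(d)])


def default_frequency_grid(fs: float, fmin: float = 1.0, fmax: float = 100.0, df: float = 1.0) -> np.ndarray:
    """1-100 Hz grid in 1 Hz steps, clipped to the Nyquist frequency."""
    fmax = min(fmax, fs / 2)
    return np.arange(fmin, fmax + df / 2, df)


def _check_freqs(freqs: np.ndarray, fs: float) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(freqs <= 0) or np.any(freqs > fs / 2 + 1e-9):
        raise ValueError("frequencies must lie in (0, fs/2]")
    return freqs


def ar_to_frequency(estimate: TvmvarEstimate, freqs: np.ndarray) -> np.ndarray:
    """Spectral coefficient matrix ``Abar(f, t)``, complex, shape (d, d, F, T).

    NaN-masked coefficient frames (filter warm-up) yield NaN output frames.
    """
    freqs = _check_freqs(freqs, estimate.fs)
    A = estimate.coefficients  # (T, p, d, d)
    T, p, d, _ = A.shape
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(k, freqs) / estimate.fs)  # (p, F)
    out = -np.einsum("tklj,kf->ljft", A, phase)
    out[np.arange(d), np.arange(d)] += 1.0
    return out


def _pdc_from_coeff_chunk(A: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Squared row-normalized PDC for a time chunk of coefficients (T, p, d, d)."""
    d = A.shape[2]
    ab = -np.einsum("tklj,kf->ljft", A, phase)
    ab[np.arange(d), np.arange(d)] += 1.0
    power = np.abs(ab) ** 2
    denom = power.sum(axis=1, keepdims=True)
    return power / denom


def pdc(estimate: TvmvarEstimate, freqs: np.ndarray | None = None, chunk: int = 64) -> SpectralConnectivity:
    """Squared row-normalized partial directed coherence, shape (d, d, F, T).

    Entry ``[l, j, f, t]`` is the squared influence of source j on target l
    normalized by target l's total inflow at that frequency, so that
    ``sum_j pdc[l, j, f, t] = 1``.  Computed in time chunks to bound memory.
    """
    if freqs is None:
        freqs = default_frequency_grid(estimate.fs)
    freqs = _check_freqs(freqs, estimate.fs)
    A = estimate.coefficients
    T, p, d, _ = A.shape
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(k, freqs) / estimate.fs)
    values = np.empty((d, d, freqs.size, T))
    for start in range(0, T, chunk):
        stop = min(start + chunk, T)
        values[..., start:stop] = _pdc_from_coeff_chunk(A[start:stop], phase)
    return SpectralConnectivity(values=values, freqs=freqs, fs=estimate.fs, kind="pdc")


def estimate_innovation_covariance(estimate: TvmvarEstimate) -> np.ndarray:
    """Time-invariant innovation covariance for PSD estimation.

    Element-wise median of the per-time innovation covariance over the last
    half of valid samples (discarding the filter's adaptation stage),
    symmetrized.
    """
    valid = estimate.innovation_cov[estimate.valid_from:]
    if valid.shape[0] < 4:
        raise ValueError("need at least 4 valid time points")
    half = valid[valid.shape[0] // 2:]
    sigma = np.median(half, axis=0)
    return 0.5 * (sigma + sigma.T)


def psd(
    estimate: TvmvarEstimate,
    freqs: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> SpectralConnectivity:
    """Parametric time-varying cross power spectral density.

    ``PSD(f, t) = B(f, t) Sigma B(f, t)*`` with ``B = Abar^-1``; the innovation
    covariance defaults to :func:`estimate_innovation_covariance`.  Singular
    spectral matrices produce NaN frames with a warning.
    """
    if freqs is None:
        freqs = default_frequency_grid(estimate.fs)
    freqs = _check_freqs(freqs, estimate.fs)
    if sigma is None:
        sigma = estimate_innovation_covariance(estimate)
    ab = ar_to_frequency(estimate, freqs)  # (d, d, F, T)
    d = ab.shape[0]
    abm = ab.transpose(3, 2, 0, 1)  # (T, F, d, d)
    values = np.full_like(abm, np.nan, dtype=complex)
    finite = np.isfinite(abm).all(axis=(2, 3))
    n_singular = 0
    for t, f in np.argwhere(finite):
        try:
            B = np.linalg.inv(abm[t, f])
        except np.linalg.LinAlgError:
            n_singular += 1
            continue
        values[t, f] = B @ sigma @ B.conj().T
    if n_singular:
        warnings.warn(f"singular spectral matrix at {n_singular} (f, t) points; NaN emitted")
    return SpectralConnectivity(
        values=values.transpose(2, 3, 1, 0), freqs=freqs, fs=estimate.fs, kind="psd"
    )


def check_pdc_row_sums(conn: SpectralConnectivity) -> None:
    """Assert the PDC row-normalization invariant (sums to 1 within 1e-9)."""
    if conn.kind != "pdc":
        raise ValueError("row-sum check applies to PDC only")
    sums = conn.values.sum(axis=1)
    finite = np.isfinite(sums)
    if not np.allclose(sums[finite], 1.0, atol=_ROW_SUM_TOL):
        raise AssertionError("PDC rows do not sum to 1 within tolerance")
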