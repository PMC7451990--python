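"""Shared data model for multi-trial time-varying MVAR estimation.

A multi-trial recording is treated as ``N`` realizations of the same
``d``-dimensional stochastic process sampled at ``fs`` Hz.  Its dynamics are
modeled by a time-varying multivariate autoregression (tvMVAR)

    Y_t = sum_{k=1..p} A_{k,t} Y_{t-k} + eps_t

where ``A_{k,t}`` are (d x d) coefficient matrices and ``eps_t`` is the
innovation process.  Both filters in this package estimate the stacked state
matrix ``x_t`` (shape ``(d*p, d)``) whose row block ``k`` holds ``A_{k,t}^T``,
so that the measurement equation reads ``z_t = H_t x_t`` with ``z_t`` the
(N x d) matrix of current samples and ``H_t`` the (N x d*p) lag matrix of the
``p`` most recent past samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class WindowUnderflowError(ValueError):
    """Raised when a lag window of length ``p`` does not fit before ``t``."""


class DimensionError(ValueError):
    """Raised on a shape mismatch between state and coefficient layouts."""


@dataclass
class MultiTrialTimeSeries:
    """Multi-trial recording: ``data`` has shape (N trials, d channels, T samples).

    Parameters
    ----------
    data:
        Real array of shape ``(N, d, T)``; all values must be finite.
    fs:
        Sampling rate in Hz.
    channel_labels:
        Optional channel names (length ``d``); defaults to ``ch0..ch{d-1}``.
    time:
        Time axis in seconds (length ``T``, step ``1/fs``, may start negative
        for pre-stimulus baselines); defaults to ``arange(T)/fs``.
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str] | None = None
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        n, d, t = self.data.shape
        if n < 1 or d < 2 or t < 2:
            raise ValueError(f"need N>=1, d>=2, T>=2; got N={n}, d={d}, T={t}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(d)]
        elif len(self.channel_labels) != d:
            raise ValueError("channel_labels length must equal the channel count")
        if self.time is None:
            self.time = np.arange(t) / self.fs
        else:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != (t,):
                raise ValueError("time must have length T")
            steps = np.diff(self.time)
            if np.any(steps <= 0) or not np.allclose(steps, 1.0 / self.fs, rtol=1e-6):
                raise ValueError("time must increase strictly with step 1/fs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class TvmvarEstimate:
    """Filter output: time-resolved AR coefficients plus innovation statistics.

    ``coefficients`` has shape ``(T, p, d, d)`` with entry ``[t, k, l, j]`` the
    influence of channel ``j`` at lag ``k+1`` on channel ``l`` at time ``t``.
    Samples before ``valid_from`` (no full lag window) are NaN-masked.
    ``innovation_cov`` holds the per-time innovation covariance estimate
    (adaptive R for the Kalman filter, residual covariance for STOK) and
    ``c_trajectory`` the adaptation constant actually used at each sample
    (constant for the Kalman filter, self-tuned for STOK).
    """

    coefficients: np.ndarray
    order: int
    innovation_cov: np.ndarray
    c_trajectory: np.ndarray
    fs: float
    valid_from: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, p, d, d2 = self.coefficients.shape
        if d != d2 or p != self.order:
            raise DimensionError("coefficients must have shape (T, p, d, d)")
        if self.innovation_cov.shape != (t, d, d):
            raise DimensionError("innovation_cov must have shape (T, d, d)")
        if self.c_trajectory.shape != (t,):
            raise DimensionError("c_trajectory must have length T")
        valid = self.c_trajectory[self.valid_from:]
        if valid.size and (np.any(valid <= 0) or np.any(valid > 1)):
            raise ValueError("c_trajectory entries must lie in (0, 1]")

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[2]

    @property
    def n_samples(self) -> int:
        return self.coefficients.shape[0]


def build_lag_matrix(Y: MultiTrialTimeSeries, t: int, p: int) -> np.ndarray:
    """Lag (design) matrix ``H_t = (Y_{t-1}, ..., Y_{t-p})`` of shape (N, d*p).

    Column block ``k`` (0-based, width ``d``) holds all trials of the signal at
    time ``t - (k+1)``, so that ``z_t = H_t x_t`` reproduces the tvMVAR model
    when ``x_t`` stacks the transposed coefficient matrices.
    """
    if p < 1:
        raise ValueError("order p must be >= 1")
    if t < p:
        raise WindowUnderflowError(
            f"t={t} has no full lag window of length p={p}; earliest valid t is {p}"
        )
    # data[:, :, t-p:t] reversed along time gives blocks (t-1, t-2, ..., t-p)
    window = Y.data[:, :, t - p:t][:, :, ::-1]
    return window.transpose(0, 2, 1).reshape(Y.n_trials, Y.n_channels * p)


def state_to_coefficients(x: np.ndarray, d: int, p: int) -> np.ndarray:
    """Unstack the state matrix (d*p, d) into the coefficient slice (p, d, d).

    ``A_k[l, j] = x[(k-1)*d + j, l]`` — the state's column ``l`` holds the
    regression weights predicting channel ``l``.
    """
    x = np.asarray(x)
    if x.shape != (d * p, d):
        raise DimensionError(f"state must have shape ({d * p}, {d}); got {x.shape}")
    return x.reshape(p, d, d).transpose(0, 2, 1)


def coefficients_to_state(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`state_to_coefficients`: (p, d, d) -> (d*p, d)."""
    coeffs = np.asarray(coeffs)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise DimensionError("coefficients must have shape (p, d, d)")
    p, d, _ = coeffs.shape
    return coeffs.transpose(0, 2, 1).reshape(d * p, d)


def _pooled_ols(Y: MultiTrialTimeSeries, times: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled multi-trial OLS fit of a stationary MVAR(p) on given time points.

    Trials x time points are stacked as independent regression rows.  Returns
    (state matrix, residual matrix, number of rows).
    """
    H = np.concatenate([build_lag_matrix(Y, t, p) for t in times], axis=0)
    Z = np.concatenate([Y.data[:, :, t] for t in times], axis=0)
    x, *_ = np.linalg.lstsq(H, Z, rcond=None)
    resid = Z - H @ x
    return x, resid, H.shape[0]


def fit_stationary_mvar(Y: MultiTrialTimeSeries, window: tuple[int, int], p: int) -> np.ndarray:
    """Pooled-OLS stationary MVAR(p) coefficients (p, d, d) on a sample window."""
    t0, t1 = window
    times = np.arange(max(t0, p) + 0, t1)
    times = times[times >= p]
    if times.size == 0:
        raise ValueError("window leaves no valid regression time points")
    x, _, _ = _pooled_ols(Y, times, p)
    return state_to_coefficients(x, Y.n_channels, p)


def select_model_order_fpe(
    Y: MultiTrialTimeSeries, window: tuple[int, int], p_max: int
) -> int:
    """Select the MVAR model order by Akaike's final prediction error (FPE).

    For each candidate order ``p`` a stationary MVAR is fitted by pooled OLS on
    the window (trials stacked as rows, only times ``t >= t0 + p_max`` so every
    order sees the same samples) and

        FPE(p) = det(Sigma_eps(p)) * ((M + d*p + 1) / (M - d*p - 1))**d

    is evaluated with ``M`` the number of regression rows.  Returns the
    minimizing order; candidate orders whose regression is ill-conditioned are
    skipped with a warning.
    """
    t0, t1 = window
    d = Y.n_channels
    times = np.arange(max(t0 + p_max, p_max), t1)
    if times.size == 0:
        raise ValueError("window too short for p_max")
    best_p, best_fpe = None, np.inf
    for p in range(1, p_max + 1):
        M = Y.n_trials * times.size
        if M - d * p - 1 <= 0:
            warnings.warn(f"order {p}: not enough rows (M={M}); skipped")
            continue
        try:
            _, resid, M = _pooled_ols(Y, times, p)
            sigma = resid.T @ resid / M
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0 or not np.isfinite(logdet):
                raise np.linalg.LinAlgError("singular residual covariance")
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"order {p} skipped: {exc}")
            continue
        log_fpe = logdet + d * (np.log(M + d * p + 1) - np.log(M - d * p - 1))
        if log_fpe < best_fpe:
            best_p, best_fpe = p, log_fpe
    if best_p is None:
        raise RuntimeError("FPE selection failed at every candidate order")
    return best_p
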