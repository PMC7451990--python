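"""Self-tuning optimized Kalman (STOK) filter for tvMVAR estimation.

STOK replaces explicit noise-covariance modeling with a least-squares gain:
under the assumption that the projected error covariance is proportional to
the measurement noise covariance, the Kalman update collapses to an
exponential moving average between the previous state and the instantaneous
least-squares reconstruction,

    x+_t = (x+_{t-1} + c_t * Hpinv_t z_t) / (1 + c_t).

Two ingredients make the filter robust and fast:

* the pseudo-inverse is regularized by damped SVD — singular components are
  shrunk by filter factors ``s / (s^2 + lambda)`` with ``lambda`` chosen per
  time step so that the retained components explain at least a fraction
  ``theta`` (default 0.99) of the total variance of the lag matrix;
* the memory decay ``c_t`` is self-tuned at each step from the proportional
  change in innovation residuals between two consecutive non-overlapping data
  segments of length ~p, clipped to ``[b, 1-b]`` (default b = 0.05): when a
  model fitted to the immediate past stops explaining incoming data, the
  residual trace jumps and the filter speeds up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MultiTrialTimeSeries, TvmvarEstimate, build_lag_matrix, state_to_coefficients

logger = logging.getLogger(__name__)

_SEGMENT = "segment"
_PER_SAMPLE = "per_sample"


@dataclass
class StokConfig:
    """STOK filter configuration.

    ``b`` is the baseline memory-decay constant bounding ``c_t`` away from 0
    and 1; ``theta`` the retained-variance fraction of the damped-SVD
    regularization (``theta=1`` disables regularization).  ``fixed_c``
    bypasses self-tuning with a constant decay (ablation comparator), and
    ``residual_strategy`` chooses how segment residuals are obtained:
    ``"segment"`` fits one pooled least-squares model per segment (sensitive
    to coefficient changes inside the segment), ``"per_sample"`` averages the
    residuals of instantaneous per-sample fits.
    """

    order: int
    b: float = 0.05
    theta: float = 0.99
    x0: np.ndarray | None = None
    fixed_c: float | None = None
    residual_strategy: str = _SEGMENT

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.b < 0.5:
            raise ValueError("baseline constant b must lie in (0, 0.5)")
        if not 0 < self.theta <= 1:
            raise ValueError("variance threshold theta must lie in (0, 1]")
        if self.fixed_c is not None and not 0 < self.fixed_c <= 1:
            raise ValueError("fixed_c must lie in (0, 1]")
        if self.residual_strategy not in (_SEGMENT, _PER_SAMPLE):
            raise ValueError(f"unknown residual strategy {self.residual_strategy!r}")


@dataclass
class DampedPinv:
    """Damped-SVD pseudo-inverse of a lag matrix.

    ``pinv`` has shape (d*p, N); ``lam`` is the damping parameter (the squared
    first excluded singular value, 0 if everything is retained),
    ``n_retained`` the number of components above the variance knee and
    ``variance_explained`` their cumulative energy fraction.
    """

    pinv: np.ndarray
    lam: float
    n_retained: int
    variance_explained: float


def damped_pseudoinverse(H: np.ndarray, theta: float = 0.99) -> DampedPinv:
    """Regularized pseudo-inverse with variance-based damping.

    Computes the thin SVD ``H = U S V'``, finds the smallest component count
    ``k`` whose energy fractions ``s_i^2 / sum s_j^2`` cumulate to at least
    ``theta``, sets ``lambda = s_{k+1}^2`` (0 when all components are
    retained) and returns ``V diag(s_i / (s_i^2 + lambda)) U'``.  The filter
    factors never exceed ``1/s_i`` (pure shrinkage); zero singular values
    contribute nothing.
    """
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("lag matrix contains non-finite values")
    if not np.any(H):
        raise ValueError("lag matrix is identically zero")
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    energy = s**2
    frac = energy / energy.sum()
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, theta - 1e-12)) + 1
    tol = s[0] * max(H.shape) * np.finfo(float).eps
    n_pos = int(np.count_nonzero(s > tol))
    k = min(k, n_pos)
    lam = float(s[k] ** 2) if k < n_pos else 0.0
    factors = np.divide(s, energy + lam, out=np.zeros_like(s), where=s > tol)
    pinv = (Vt.T * factors) @ U.T
    return DampedPinv(pinv=pinv, lam=lam, n_retained=k, variance_explained=float(cum[k - 1]))


def _segment_samples(t: int, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample indices of the NEW (t-p..t) and OLD (t-2p..t-p-1) segments,
    clipped to times with a full lag window (s >= p)."""
    new = np.arange(max(t - p, p), t + 1)
    old = np.arange(max(t - 2 * p, p), t - p)
    return new, old


def _clip_c(ratio: float, b: float) -> float:
    return float(min(b + ratio, 1.0 - b))


def _c_from_traces(tr_new: float, tr_old: float, b: float, t: int) -> float:
    """Map the proportional residual-trace change to a decay constant.

    A vanishing OLD trace with non-vanishing NEW trace means the past was
    perfectly predictable and the present is not: track at maximal speed.
    Both traces zero (e.g. silent data) leave the filter at baseline speed.
    """
    if tr_old <= 0:
        if tr_new <= 0:
            return b
        logger.info("zero OLD residual trace at t=%d; c set to 1-b", t)
        return 1.0 - b
    return _clip_c(abs(tr_new - tr_old) / tr_old, b)


def self_tuning_c(
    Y: MultiTrialTimeSeries,
    p: int,
    t: int,
    b: float = 0.05,
    theta: float = 0.99,
    strategy: str = _SEGMENT,
) -> float:
    """Self-tuned memory decay ``c_t`` at a single time step.

    Compares the innovation-residual traces of two consecutive non-overlapping
    segments (NEW: ``t-p..t``, OLD: ``t-2p..t-p-1``) of regularized
    least-squares fits and returns
    ``min(b + |tr_new - tr_old| / tr_old, 1 - b)``; during warm-up (OLD
    segment not yet available) returns ``b``.
    """
    n = Y.n_trials
    new, old = _segment_samples(t, p)
    if old.size == 0 or new.size == 0:
        return b

    def seg_trace(samples: np.ndarray) -> float:
        if strategy == _PER_SAMPLE:
            traces = []
            for s in samples:
                H = build_lag_matrix(Y, s, p)
                z = Y.data[:, :, s]
                if not np.any(H):
                    traces.append(float(np.sum(z**2)) / (n - 1))
                    continue
                E = z - H @ (damped_pseudoinverse(H, theta).pinv @ z)
                traces.append(float(np.sum(E**2)) / (n - 1))
            return float(np.mean(traces))
        H = np.concatenate([build_lag_matrix(Y, s, p) for s in samples], axis=0)
        Z = np.concatenate([Y.data[:, :, s] for s in samples], axis=0)
        if not np.any(H):
            rss = float(np.sum(Z**2))
        else:
            x, *_ = np.linalg.lstsq(H, Z, rcond=None)
            rss = float(np.sum((Z - H @ x) ** 2))
        return max(rss, 0.0) / ((n - 1) * samples.size)

    return _c_from_traces(seg_trace(new), seg_trace(old), b, t)


def stok_filter(Y: MultiTrialTimeSeries, config: StokConfig) -> TvmvarEstimate:
    """Run the STOK filter and return the tvMVAR estimate.

    For each ``t >= p``: build the lag matrix, form its damped pseudo-inverse,
    self-tune ``c_t`` from segment residuals, and update the state as the
    ``c_t``-weighted average of the previous state and the instantaneous
    regularized least-squares solution.  Output frames before ``t = p`` are
    NaN-masked.  Diagnostics record the damping parameter, retained component
    count and variance fraction per time step, plus the relative error
    variance of one-step predictions.
    """
    if not np.all(np.isfinite(Y.data)):
        raise ValueError("input contains non-finite values")
    p, b, theta = config.order, config.b, config.theta
    n, d, T = Y.data.shape
    if n < 2:
        raise ValueError("need at least 2 trials")
    if T <= p:
        raise ValueError("need more samples than the model order")
    dp = d * p
    pooled = config.residual_strategy == _SEGMENT

    x = np.zeros((dp, d)) if config.x0 is None else np.array(config.x0, dtype=float)
    coeffs = np.full((T, p, d, d), np.nan)
    innov_cov = np.full((T, d, d), np.nan)
    c_traj = np.full(T, b)
    lam_traj = np.full(T, np.nan)
    nret_traj = np.full(T, np.nan)
    var_traj = np.full(T, np.nan)
    pred_sq = np.zeros(T)
    meas_sq = np.zeros(T)

    # per-sample sufficient statistics for the segment residual monitor
    gram = np.zeros((T, dp, dp)) if pooled else None
    cross = np.zeros((T, dp, d)) if pooled else None
    zsq = np.zeros(T)
    sample_trace = np.zeros(T)

    def pooled_trace(samples: np.ndarray) -> float:
        G = gram[samples].sum(axis=0)
        C = cross[samples].sum(axis=0)
        total = zsq[samples].sum()
        if not np.any(G):
            rss = total
        else:
            xs = np.linalg.pinv(G, hermitian=True) @ C
            rss = total - float(np.sum(xs * C))
        return max(rss, 0.0) / ((n - 1) * samples.size)

    for t in range(p, T):
        H = build_lag_matrix(Y, t, p)
        z = Y.data[:, :, t]
        zsq[t] = float(np.sum(z**2))
        if np.any(H):
            dpinv = damped_pseudoinverse(H, theta)
            x_ls = dpinv.pinv @ z
            lam_traj[t], nret_traj[t], var_traj[t] = (
                dpinv.lam, dpinv.n_retained, dpinv.variance_explained,
            )
        else:
            x_ls = np.zeros((dp, d))
            lam_traj[t], nret_traj[t], var_traj[t] = 0.0, 0, 1.0
        if pooled:
            gram[t] = H.T @ H
            cross[t] = H.T @ z
        else:
            E_ls = z - H @ x_ls
            sample_trace[t] = float(np.sum(E_ls**2)) / (n - 1)

        if config.fixed_c is not None:
            c_t = config.fixed_c
        else:
            new, old = _segment_samples(t, p)
            if old.size == 0:
                c_t = b
            elif pooled:
                c_t = _c_from_traces(pooled_trace(new), pooled_trace(old), b, t)
            else:
                c_t = _c_from_traces(
                    float(sample_trace[new].mean()), float(sample_trace[old].mean()), b, t
                )
            assert b <= c_t <= 1 - b, "self-tuned c escaped its clipping range"

        E_pred = z - H @ x
        pred_sq[t] = float(np.sum(E_pred**2))
        meas_sq[t] = zsq[t]
        x = (x + c_t * x_ls) / (1.0 + c_t)
        if not np.isfinite(x).all():
            raise FloatingPointError(f"non-finite state at t={t}")
        coeffs[t] = state_to_coefficients(x, d, p)
        E = z - H @ x
        innov_cov[t] = E.T @ E / (n - 1)
        c_traj[t] = c_t

    denom = meas_sq[p:].sum()
    rev = pred_sq[p:].sum() / denom if denom > 0 else np.inf
    return TvmvarEstimate(
        coefficients=coeffs,
        order=p,
        innovation_cov=innov_cov,
        c_trajectory=c_traj,
        fs=Y.fs,
        valid_from=p,
        diagnostics={
            "lambda": lam_traj,
            "n_retained": nret_traj,
            "variance_explained": var_traj,
            "rev": rev,
            "prediction_sq": pred_sq,
            "measurement_sq": meas_sq,
        },
    )
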