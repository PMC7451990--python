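"""General linear Kalman filter for multi-trial tvMVAR estimation.

The state (the stacked AR coefficient matrix) follows a first-order random
walk: the transition matrix is the identity and the process noise covariance
is replaced by a rate-of-change term ``c**2 * I`` added to the predicted error
covariance.  The measurement noise covariance is approximated adaptively from
the measurement innovations, entering the gain only through its trace.  The
adaptation constant ``c`` is the single free parameter trading tracking speed
against smoothness; it is held fixed over time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import MultiTrialTimeSeries, TvmvarEstimate, build_lag_matrix, state_to_coefficients

logger = logging.getLogger(__name__)

#: condition number above which the innovation matrix is inverted by pseudo-inverse
_COND_LIMIT = 1e12


@dataclass
class KfConfig:
    """Configuration of the general linear Kalman filter.

    ``c`` is the adaptation constant in (0, 1]; the rate-of-change constant C
    multiplying the process-noise surrogate is tied to ``c`` unless
    ``rate_constant`` is set explicitly.
    """

    order: int
    c: float = 0.02
    rate_constant: float | None = None
    x0: np.ndarray | None = None
    P0: np.ndarray | None = None
    R0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.c <= 1:
            raise ValueError("adaptation constant c must lie in (0, 1]")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def kf_filter(Y: MultiTrialTimeSeries, config: KfConfig) -> TvmvarEstimate:
    """Run the multi-trial Kalman filter and return the tvMVAR estimate.

    At each time ``t >= p`` the filter (i) predicts the state by the random
    walk ``x- = x+``, ``P- = P+ + C^2 I``; (ii) forms the innovations
    ``E = z_t - H_t x-`` and updates the adaptive measurement noise
    ``R_t = R_{t-1} + c (E'E/(N-1) - R_{t-1})``; (iii) computes the gain
    ``K = P- H' (H P- H' + tr(R_t) I_N)^-1``; (iv) updates
    ``x+ = x- + K E`` and ``P+ = (I - K H) P-`` (symmetrized).

    Output frames before ``t = p`` are NaN-masked.  The per-time prediction
    residual energy is stored under ``diagnostics['rev']`` together with the
    relative error variance of the whole run.
    """
    if not np.all(np.isfinite(Y.data)):
        raise ValueError("input contains non-finite values")
    p, c = config.order, config.c
    rate = c if config.rate_constant is None else config.rate_constant
    n, d, T = Y.data.shape
    if n < 2:
        raise ValueError("need at least 2 trials for the innovation covariance")
    if T <= p:
        raise ValueError("need more samples than the model order")
    dp = d * p

    x = np.zeros((dp, d)) if config.x0 is None else np.array(config.x0, dtype=float)
    P = np.eye(dp) if config.P0 is None else np.array(config.P0, dtype=float)
    R = np.eye(d) if config.R0 is None else np.array(config.R0, dtype=float)

    coeffs = np.full((T, p, d, d), np.nan)
    innov_cov = np.full((T, d, d), np.nan)
    pred_sq = np.zeros(T)
    meas_sq = np.zeros(T)
    eye_n = np.eye(n)
    eye_dp = np.eye(dp)

    n_fallback = 0
    for t in range(p, T):
        H = build_lag_matrix(Y, t, p)
        z = Y.data[:, :, t].copy()
        # predict (identity transition, rate-of-change process noise)
        P_pred = P + rate**2 * eye_dp
        E = z - H @ x
        sigma_r = E.T @ E / (n - 1)
        R = R + c * (sigma_r - R)
        S = H @ P_pred @ H.T + np.trace(R) * eye_n
        S = 0.5 * (S + S.T)
        PHt = P_pred @ H.T
        try:
            if np.linalg.cond(S) > _COND_LIMIT:
                raise np.linalg.LinAlgError("ill-conditioned innovation matrix")
            K = np.linalg.solve(S, PHt.T).T
        except np.linalg.LinAlgError:
            n_fallback += 1
            K = PHt @ np.linalg.pinv(S)
        x = x + K @ E
        P = (eye_dp - K @ H) @ P_pred
        P = 0.5 * (P + P.T)
        if not np.isfinite(x).all():
            raise FloatingPointError(f"non-finite state at t={t}")
        coeffs[t] = state_to_coefficients(x, d, p)
        innov_cov[t] = 0.5 * (R + R.T)
        pred_sq[t] = float(np.sum(E**2))
        meas_sq[t] = float(np.sum(z**2))

    if n_fallback:
        warnings.warn(
            f"innovation matrix near-singular at {n_fallback} time steps; "
            "pseudo-inverse fallback used"
        )
    denom = meas_sq[p:].sum()
    rev = pred_sq[p:].sum() / denom if denom > 0 else np.inf
    return TvmvarEstimate(
        coefficients=coeffs,
        order=p,
        innovation_cov=innov_cov,
        c_trajectory=np.full(T, c),
        fs=Y.fs,
        valid_from=p,
        diagnostics={"rev": rev, "prediction_sq": pred_sq, "measurement_sq": meas_sq},
    )


def tune_kf_c_rev(
    Y: MultiTrialTimeSeries, p: int, c_grid: "np.ndarray | list[float]"
) -> float:
    """Pick the adaptation constant minimizing the relative error variance.

    ``REV(c) = sum_t ||z_t - H_t x-_t||_F^2 / sum_t ||z_t||_F^2`` over valid
    times; ties resolve to the smallest grid value.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if c_grid.size == 0:
        raise ValueError("c_grid must be nonempty")
    if np.any((c_grid <= 0) | (c_grid > 1)):
        raise ValueError("grid values must lie in (0, 1]")
    best_c, best_rev = None, np.inf
    for c in np.sort(c_grid):
        rev = kf_filter(Y, KfConfig(order=p, c=float(c))).diagnostics["rev"]
        logger.info("REV(c=%g) = %g", c, rev)
        if np.isfinite(rev) and rev < best_rev:
            best_c, best_rev = float(c), rev
    if best_c is None:
        raise RuntimeError("REV was non-finite for every grid value")
    return best_c
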