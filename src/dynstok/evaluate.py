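"""Validation machinery: ROC/AUC against ground truth, band flows, statistics.

Detection performance of an estimated connectivity tensor is quantified by
binarizing the ground-truth PDC (any cell > 0 counts as a true connection, or
only cells above its median) and sweeping twenty equally spaced quantile
criteria (1st to 99th) over the pooled estimated off-diagonal PDC
distribution; sensitivity/specificity per criterion trace a ROC curve whose
area (AUC) summarizes performance independently of the estimate's scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TvmvarEstimate
from .simulate import GroundTruthModel
from .spectral import SpectralConnectivity, pdc

_GT_TOL = 1e-12
GT_RULES = ("greater_than_zero", "quantile_0.5")


@dataclass
class RocResult:
    """ROC sweep over quantile criteria plus its AUC."""

    criteria: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    gt_threshold_rule: str

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if np.any((v < 0) | (v > 1)):
                raise ValueError("sensitivity/specificity must lie in [0, 1]")
        if not 0 <= self.auc <= 1:
            raise ValueError("auc must lie in [0, 1]")


@dataclass
class FlowSeries:
    """Per-node summed outflow (or inflow) time course in a frequency band."""

    values: np.ndarray  # (d, T)
    band: tuple[float, float]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("outflow", "inflow"):
            raise ValueError("kind must be 'outflow' or 'inflow'")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < -1e-12):
            raise ValueError("summed PDC flows must be nonnegative")


def ground_truth_pdc(
    model: GroundTruthModel, freqs: np.ndarray | None = None
) -> SpectralConnectivity:
    """PDC computed directly from the simulated coefficient trajectory."""
    T, p, d, _ = model.coefficients.shape
    estimate = TvmvarEstimate(
        coefficients=model.coefficients,
        order=p,
        innovation_cov=np.broadcast_to(np.eye(d), (T, d, d)).copy(),
        c_trajectory=np.ones(T),
        fs=model.fs,
        valid_from=0,
    )
    return pdc(estimate, freqs)


def _offdiag_values(conn: SpectralConnectivity) -> np.ndarray:
    d = conn.n_channels
    mask = ~np.eye(d, dtype=bool)
    return conn.values[mask].ravel()


def pooled_offdiag_cells(
    gt: SpectralConnectivity, est: SpectralConnectivity
) -> tuple[np.ndarray, np.ndarray]:
    """Matched pooled off-diagonal (l, j, f, t) cells, non-finite cells dropped."""
    if gt.values.shape != est.values.shape:
        raise ValueError("ground truth and estimate shapes differ")
    g, e = _offdiag_values(gt), _offdiag_values(est)
    keep = np.isfinite(g) & np.isfinite(e)
    return g[keep], e[keep]


def roc_auc_values(
    gt_values: np.ndarray,
    est_values: np.ndarray,
    gt_rule: str = "greater_than_zero",
    n_criteria: int = 20,
) -> RocResult:
    """ROC/AUC from pooled cell value arrays (see :func:`roc_auc`)."""
    if gt_rule not in GT_RULES:
        raise ValueError(f"gt_rule must be one of {GT_RULES}")
    if gt_rule == "greater_than_zero":
        truth = gt_values > _GT_TOL
    else:
        positives = gt_values[gt_values > _GT_TOL]
        if positives.size == 0:
            raise ValueError("ground truth has no positive cells")
        truth = gt_values > np.quantile(positives, 0.5)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ground truth is all-positive or all-zero; ROC undefined")

    levels = np.linspace(0.01, 0.99, n_criteria)
    est_sorted = np.sort(est_values)
    thresholds = np.quantile(est_sorted, levels)  # sorted input: cheap
    # predicted-positive = value > threshold; count via sorted positive/negative pools
    pos_sorted = np.sort(est_values[truth])
    neg_sorted = np.sort(est_values[~truth])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="right")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="right")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    x = np.concatenate(([0.0], 1.0 - spec, [1.0]))
    y = np.concatenate(([0.0], sens, [1.0]))
    order = np.lexsort((y, x))
    auc = float(np.trapezoid(y[order], x[order]))
    return RocResult(
        criteria=levels, sensitivity=sens, specificity=spec,
        auc=min(max(auc, 0.0), 1.0), gt_threshold_rule=gt_rule,
    )


def roc_auc(
    gt: SpectralConnectivity,
    est: SpectralConnectivity,
    gt_rule: str = "greater_than_zero",
    n_criteria: int = 20,
) -> RocResult:
    """Quantile-criterion ROC of an estimated PDC against the ground truth.

    Off-diagonal (l, j, f, t) cells are pooled; the ground truth is binarized
    by ``gt_rule`` and the estimate swept over ``n_criteria`` equally spaced
    quantile criteria; AUC is the trapezoid area of the resulting curve with
    (0, 0) and (1, 1) anchors.  Diagonal (self-influence) cells are excluded.
    """
    g, e = pooled_offdiag_cells(gt, est)
    return roc_auc_values(g, e, gt_rule=gt_rule, n_criteria=n_criteria)


def strongest_connection_subset(
    gt: SpectralConnectivity, est: SpectralConnectivity, q: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict pooled ROC cells to the strongest ground-truth connections.

    Keeps zero-ground-truth cells plus the nonzero cells whose magnitude
    exceeds the ``q`` quantile of nonzero ground-truth values, so weak true
    connections neither count as hits nor as false alarms.
    """
    g, e = pooled_offdiag_cells(gt, est)
    nonzero = g > _GT_TOL
    if not np.any(nonzero):
        raise ValueError("no nonzero ground-truth cells")
    thr = np.quantile(g[nonzero], q)
    keep = ~nonzero | (g > thr)
    if not np.any(keep & nonzero):
        raise ValueError("strongest-connection subset is empty")
    return g[keep], e[keep]


def summed_flow(
    conn: SpectralConnectivity, band: tuple[float, float] = (40.0, 90.0), kind: str = "outflow"
) -> FlowSeries:
    """Per-node summed PDC outflow (or inflow) in a frequency band.

    Outflow of node j at time t sums the band-averaged PDC from j to every
    other target; inflow of node l sums over sources.  Total outflow equals
    total inflow at every time point.
    """
    f_lo, f_hi = band
    sel = (conn.freqs >= f_lo) & (conn.freqs <= f_hi)
    if not np.any(sel):
        raise ValueError(f"band {band} contains no grid frequencies")
    band_mean = conn.values[:, :, sel, :].mean(axis=2)  # (d, d, T)
    d = band_mean.shape[0]
    off = ~np.eye(d, dtype=bool)
    masked = np.where(off[:, :, None], band_mean, 0.0)
    axis = 0 if kind == "outflow" else 1
    return FlowSeries(values=masked.sum(axis=axis), band=(f_lo, f_hi), kind=kind)


def baseline_zscore(
    x: np.ndarray, time: np.ndarray, baseline: tuple[float, float] = (-0.1, 0.0)
) -> np.ndarray:
    """Z-score a time-resolved tensor against a baseline interval (seconds).

    The last axis of ``x`` is time; each remaining cell is standardized by its
    baseline mean and standard deviation.  Zero-variance cells become NaN.
    """
    time = np.asarray(time)
    lo, hi = baseline
    sel = (time >= lo) & (time <= hi)
    if int(sel.sum()) < 3:
        raise ValueError("baseline must contain at least 3 samples")
    base = x[..., sel]
    mean = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, ddof=1, keepdims=True)
    zero = sd == 0
    if np.any(zero):
        warnings.warn("zero baseline variance in some cells; NaN emitted")
        sd = np.where(zero, np.nan, sd)
    return (x - mean) / sd


def global_connectivity(pdc_z: np.ndarray) -> np.ndarray:
    """Mean over all off-diagonal (l, j) pairs of a (d, d, F, T) tensor -> (F, T)."""
    d = pdc_z.shape[0]
    mask = ~np.eye(d, dtype=bool)
    return pdc_z[mask].mean(axis=0)


def bootstrap_difference_test(
    samples: np.ndarray,
    reference: np.ndarray,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time bootstrap test of ``samples`` against ``reference``.

    ``samples`` and ``reference`` are (S subjects, T times).  At each time
    point subjects are resampled with replacement ``n_boot`` times; the
    two-sided p-value is twice the fraction of bootstrap mean differences on
    the non-dominant side of zero, floored at ``1/n_boot``.  Returns
    ``(mask, p_values)`` with ``mask = p < alpha``.
    """
    samples = np.asarray(samples, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if samples.shape != reference.shape or samples.ndim != 2:
        raise ValueError("samples and reference must both be (S, T)")
    S, T = samples.shape
    if S < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    diffs = samples - reference
    idx = rng.integers(0, S, size=(n_boot, S))
    counts = np.zeros((n_boot, S))
    np.add.at(counts, (np.arange(n_boot)[:, None], idx), 1.0)
    boot_means = counts @ diffs / S  # (n_boot, T)
    frac_le = np.mean(boot_means <= 0, axis=0)
    frac_ge = np.mean(boot_means >= 0, axis=0)
    p = 2.0 * np.minimum(frac_le, frac_ge)
    p = np.clip(p, 1.0 / n_boot, 1.0)
    degenerate = np.all(diffs == diffs[0], axis=0) & (diffs[0] == 0)
    p[degenerate] = 1.0
    return p < alpha, p
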