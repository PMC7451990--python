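"""Ground-truth generators for validating tvMVAR filters.

The surrogate-network framework emulates event-related cortical dynamics: a
``d``-node network with a fixed structural skeleton (60-80% of all directed
pairs) in which half of the existing links carry directed interactions.  Each
node has a positive diagonal AR(2) pair (low-frequency oscillatory dynamics)
on lags 1-2; each dynamic link carries a signed AR(2)-style pair at a random
delay of 1-5 samples (so the true order is 6).  Off-diagonal structure and
magnitudes are redrawn in each of three quasi-stationary regimes of random
onset (>= 150 ms each), with coefficients rejection-resampled until the
companion matrix of every regime is stable.  Trials are driven by unit
variance white noise with a small imposed cross-trial correlation
(mean 0.1, sd 0.07).

Corruption operators add white observation noise at a given signal-to-noise
power ratio and instantaneous spatial mixing by a Gaussian point-spread
kernel on a 150 x 150 mm grid, mimicking volume conduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MultiTrialTimeSeries

#: minimal regime duration (seconds)
_MIN_REGIME_S = 0.150
#: true model order of the reduced AR(6) surrogate process
TRUE_ORDER = 6


@dataclass
class GroundTruthModel:
    """Simulator output: true time-varying coefficients plus structure.

    ``coefficients`` has shape (T, p_true, d, d); ``structural_mask`` marks
    physically existing links (diagonal always true), ``dynamic_mask`` the
    subset carrying interactions; ``regime_bounds`` lists the regime edges as
    sample indices including 0 and T.
    """

    coefficients: np.ndarray
    structural_mask: np.ndarray
    dynamic_mask: np.ndarray
    regime_bounds: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        T, p, d, _ = self.coefficients.shape
        if self.structural_mask.shape != (d, d) or self.dynamic_mask.shape != (d, d):
            raise ValueError("masks must be (d, d)")
        if not np.all(self.structural_mask[self.dynamic_mask]):
            raise ValueError("dynamic links must be a subset of structural links")
        if not np.all(np.diag(self.structural_mask)):
            raise ValueError("structural mask must include the diagonal")
        off = ~np.eye(d, dtype=bool)
        nz = np.any(self.coefficients != 0, axis=(0, 1))
        if np.any(nz & off & ~self.dynamic_mask):
            raise ValueError("nonzero off-diagonal coefficients outside dynamic mask")
        bounds = np.asarray(self.regime_bounds)
        if bounds[0] != 0 or bounds[-1] != T or np.any(np.diff(bounds) <= 0):
            raise ValueError("regime_bounds must partition [0, T)")
        min_len = int(round(_MIN_REGIME_S * self.fs))
        if np.any(np.diff(bounds) < min_len):
            raise ValueError(f"every regime must last >= {min_len} samples")
        for a in bounds[:-1]:
            if not is_stable(self.coefficients[a]):
                raise ValueError(f"regime starting at sample {a} is unstable")

    @property
    def order(self) -> int:
        return self.coefficients.shape[1]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[2]

    @property
    def n_samples(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class SimulationConfig:
    """Parameters of the surrogate-network generator (defaults match the
    bundled validation experiments)."""

    d: int = 10
    n_trials: int = 200
    fs: float = 200.0
    duration: float = 2.0
    density_range: tuple[float, float] = (0.6, 0.8)
    dynamic_fraction: float = 0.5
    n_regimes: int = 3
    magnitude_range: tuple[float, float] = (0.1, 0.5)
    magnitude_step: float = 0.01
    offdiag_scale: float = 0.5
    trial_corr: tuple[float, float] = (0.1, 0.07)
    max_delay: int = 5
    seed: int | None = None
    max_iters: int = 1000

    def __post_init__(self) -> None:
        if self.d < 2 or self.n_trials < 1 or self.n_regimes < 1:
            raise ValueError("invalid size parameters")
        lo, hi = self.density_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("density range must lie in (0, 1]")
        if not 0 <= self.dynamic_fraction <= 1:
            raise ValueError("dynamic fraction must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def magnitude_grid(self) -> np.ndarray:
        lo, hi = self.magnitude_range
        n = int(round((hi - lo) / self.magnitude_step)) + 1
        return lo + self.magnitude_step * np.arange(n)


def is_stable(coeff_block: np.ndarray) -> bool:
    """Stability of a VAR(p) coefficient block (p, d, d).

    Builds the (d*p, d*p) companion matrix and checks that its spectral
    radius is below one (all eigenvalue moduli < 1).
    """
    coeff_block = np.asarray(coeff_block, dtype=float)
    p, d, _ = coeff_block.shape
    companion = np.zeros((d * p, d * p))
    companion[:d] = coeff_block.transpose(1, 0, 2).reshape(d, d * p)
    if p > 1:
        companion[d:, :-d] = np.eye(d * (p - 1))
    return bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1.0)


def _ar2_radius(a1: float, a2: float) -> float:
    """Pole radius of the scalar AR(2) model x_t = a1 x_{t-1} + a2 x_{t-2} + e."""
    return float(np.max(np.abs(np.roots([1.0, -a1, -a2]))))


#: pole-radius ceiling for diagonal AR(2) pairs and stabilized regimes
_RADIUS_CAP = 0.99


def _stabilized_block(
    diag_block: np.ndarray, off_block: np.ndarray, n_bisect: int = 20
) -> np.ndarray | None:
    """Largest coupling scale gamma <= 1 keeping ``diag + gamma*off`` stable.

    Returns the stabilized coefficient block, or None if even the diagonal
    part is unstable.  For small networks the drawn couplings are usually
    stable as-is (gamma = 1); for large dense networks the couplings are
    shrunk proportionally to the stability boundary, preserving the diagonal
    spectra and the connection structure.
    """
    if is_stable(diag_block + off_block):
        return diag_block + off_block
    if not is_stable(diag_block):
        return None
    lo, hi = 0.0, 1.0
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if is_stable(diag_block + mid * off_block):
            lo = mid
        else:
            hi = mid
    return diag_block + lo * off_block


def _draw_offdiag_block(
    rng: np.random.Generator, cfg: SimulationConfig, dynamic_mask: np.ndarray
) -> np.ndarray:
    """Signed, halved AR(2)-style pairs at random delays for dynamic links."""
    d = cfg.d
    block = np.zeros((TRUE_ORDER, d, d))
    grid = cfg.magnitude_grid
    for l, j in np.argwhere(dynamic_mask & ~np.eye(d, dtype=bool)):
        delay = rng.integers(1, cfg.max_delay + 1)  # pair occupies lags delay, delay+1
        mags = rng.choice(grid, size=2) * cfg.offdiag_scale
        signs = rng.choice([-1.0, 1.0], size=2)
        block[delay - 1, l, j] = signs[0] * mags[0]
        block[delay, l, j] = signs[1] * mags[1]
    return block


def generate_surrogate_model(config: SimulationConfig) -> GroundTruthModel:
    """Draw a regime-switching surrogate network (reduced AR(6) process).

    The structural skeleton, dynamic-link subset and diagonal AR(2) pairs are
    drawn once; off-diagonal structure and magnitudes are redrawn per regime
    and rejection-resampled until each regime's companion matrix is stable.
    Diagonal pairs are drawn from the magnitude grid subject to a pole-radius
    cap; when a coupling draw is unstable as-is (typical for dense networks
    beyond ~10 nodes, whose raw spectral radius grows with size), the
    couplings of that draw are shrunk proportionally to the stability
    boundary instead of being discarded.
    """
    rng = np.random.default_rng(config.seed)
    d, T = config.d, config.n_samples
    min_len = int(round(_MIN_REGIME_S * config.fs))
    if T < config.n_regimes * min_len:
        raise ValueError("duration too short for the requested number of regimes")

    # regime edges: uniform over feasible cut points given the 150 ms floor
    if config.n_regimes > 1:
        for _ in range(config.max_iters):
            cuts = np.sort(rng.integers(min_len, T - min_len + 1, size=config.n_regimes - 1))
            bounds = np.concatenate(([0], cuts, [T]))
            if np.all(np.diff(bounds) >= min_len):
                break
        else:
            raise RuntimeError("could not place regime boundaries")
    else:
        bounds = np.array([0, T])

    grid = config.magnitude_grid
    off = ~np.eye(d, dtype=bool)

    # structural skeleton and dynamic-link subset
    density = rng.uniform(*config.density_range)
    pairs = np.argwhere(off)
    n_struct = int(round(density * len(pairs)))
    chosen = pairs[rng.choice(len(pairs), size=n_struct, replace=False)]
    structural = np.eye(d, dtype=bool)
    structural[chosen[:, 0], chosen[:, 1]] = True
    n_dyn = int(round(config.dynamic_fraction * n_struct))
    dynamic = np.zeros((d, d), dtype=bool)
    if n_dyn:
        dyn_idx = chosen[rng.choice(n_struct, size=n_dyn, replace=False)]
        dynamic[dyn_idx[:, 0], dyn_idx[:, 1]] = True

    # positive diagonal AR(2) pairs on the magnitude grid, pole radius capped
    diag_block = np.zeros((TRUE_ORDER, d, d))
    for i in range(d):
        for attempt in range(config.max_iters):
            a1, a2 = rng.choice(grid, size=2)
            if _ar2_radius(a1, a2) < _RADIUS_CAP:
                diag_block[0, i, i], diag_block[1, i, i] = a1, a2
                break
        else:
            raise RuntimeError(f"no stable diagonal AR(2) pair found for node {i}")

    blocks = []
    for r in range(config.n_regimes):
        for attempt in range(config.max_iters):
            cand = _stabilized_block(diag_block, _draw_offdiag_block(rng, config, dynamic))
            if cand is not None and is_stable(cand):
                blocks.append(cand)
                break
        else:
            raise RuntimeError(
                f"no stable coefficient draw for regime {r} in {config.max_iters} tries"
            )

    coeffs = np.zeros((T, TRUE_ORDER, d, d))
    for block, a, b in zip(blocks, bounds[:-1], bounds[1:]):
        coeffs[a:b] = block
    return GroundTruthModel(
        coefficients=coeffs,
        structural_mask=structural,
        dynamic_mask=dynamic,
        regime_bounds=bounds,
        fs=config.fs,
    )


def _correlated_noise(
    rng: np.random.Generator, n: int, d: int, T: int, trial_corr: tuple[float, float]
) -> np.ndarray:
    """Unit-variance white noise with cross-trial correlation ~ (mean, sd).

    Each trial's noise is ``sqrt(rho_n) g + sqrt(1 - rho_n) e_n`` with a
    shared component ``g``; pairwise correlations are then
    ``sqrt(rho_n rho_m)``.  Loadings ``sqrt(rho_n)`` are drawn normal around
    ``sqrt(mean)`` with spread chosen so the product statistics approximate
    the requested mean and sd, clipped to [0, 1].
    """
    mean_r, sd_r = trial_corr
    if mean_r <= 0:
        return rng.standard_normal((n, d, T))
    mu = np.sqrt(mean_r)
    spread = sd_r / (np.sqrt(2.0) * mu) if mu > 0 else 0.0
    loading = np.clip(rng.normal(mu, spread, size=n), 0.0, 1.0)
    g = rng.standard_normal((d, T))
    e = rng.standard_normal((n, d, T))
    lam = loading[:, None, None]
    return lam * g + np.sqrt(1.0 - lam**2) * e


def simulate_trials(
    model: GroundTruthModel,
    n_trials: int,
    trial_corr: tuple[float, float] = (0.1, 0.07),
    seed: int | None = None,
) -> MultiTrialTimeSeries:
    """Simulate multi-trial realizations of a ground-truth tvMVAR process.

    All trials share the coefficient trajectory and are driven by zero-mean
    unit-variance white noise with the requested cross-trial correlation.  A
    burn-in of ``10 * p_true`` samples (first-regime coefficients) is
    discarded.
    """
    rng = np.random.default_rng(seed)
    T, p, d, _ = model.coefficients.shape
    burn = 10 * p
    eps = _correlated_noise(rng, n_trials, d, T + burn, trial_corr)
    A_ext = np.concatenate(
        [np.broadcast_to(model.coefficients[0], (burn, p, d, d)), model.coefficients], axis=0
    )
    Y = np.zeros((n_trials, d, T + burn))
    for t in range(T + burn):
        acc = eps[:, :, t].copy()
        for k in range(1, min(p, t) + 1):
            acc += Y[:, :, t - k] @ A_ext[t, k - 1].T
        Y[:, :, t] = acc
        if np.max(np.abs(acc)) > 1e6:
            raise FloatingPointError(f"trajectory diverged at sample {t - burn}")
    return MultiTrialTimeSeries(data=Y[:, :, burn:], fs=model.fs)


def add_observation_noise(
    Y: MultiTrialTimeSeries, snr_ratio: float, units: str = "linear", seed: int | None = None
) -> MultiTrialTimeSeries:
    """Add white Gaussian observation noise at a given signal-to-noise ratio.

    ``snr_ratio`` is the ratio of mean squared signal amplitude to mean
    squared noise amplitude, per channel (``units="db"`` converts decibels to
    a power ratio first).  Ratios are capped at 1e9 (effectively noiseless).
    """
    if snr_ratio <= 0:
        raise ValueError("snr_ratio must be positive")
    if units == "db":
        snr_ratio = 10.0 ** (snr_ratio / 10.0)
    elif units != "linear":
        raise ValueError("units must be 'linear' or 'db'")
    snr_ratio = min(snr_ratio, 1e9)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(Y.data.shape)
    sig_power = np.mean(Y.data**2, axis=(0, 2), keepdims=True)
    noise_power = np.mean(noise**2, axis=(0, 2), keepdims=True)
    scale = np.sqrt(sig_power / (snr_ratio * noise_power))
    return MultiTrialTimeSeries(
        data=Y.data + scale * noise, fs=Y.fs, channel_labels=Y.channel_labels, time=Y.time
    )


def apply_spatial_mixing(
    Y: MultiTrialTimeSeries, positions: np.ndarray, sigma: float
) -> MultiTrialTimeSeries:
    """Instantaneous spatial mixing by a Gaussian point-spread kernel.

    ``M_ij = exp(-|pos_i - pos_j|^2 / (2 sigma^2))`` with rows normalized to
    unit sum; every sample of every trial is premultiplied by ``M``.
    Positions are 2-D coordinates in millimeters.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (Y.n_channels, 2):
        raise ValueError("positions must have shape (d, 2)")
    dist2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    M = np.exp(-dist2 / (2.0 * sigma**2))
    M /= M.sum(axis=1, keepdims=True)
    mixed = np.einsum("ij,njt->nit", M, Y.data)
    return MultiTrialTimeSeries(
        data=mixed, fs=Y.fs, channel_labels=Y.channel_labels, time=Y.time
    )


def random_grid_positions(
    d: int, extent: float = 150.0, seed: int | None = None
) -> np.ndarray:
    """Random node locations on the square simulation grid (mm)."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, extent, size=(d, 2))


def generate_bivariate_demo(
    samples: int = 1000,
    fs: float = 200.0,
    trials: int = 200,
    diag: float = 0.9,
    coupling: float = 0.5,
    window: tuple[int, int] = (400, 600),
    seed: int | None = None,
) -> tuple[MultiTrialTimeSeries, GroundTruthModel]:
    """Two-node AR(1) demonstration with a transient directed coupling.

    Both nodes keep a constant self-coefficient ``diag``; node 2 drives node 1
    with coefficient ``coupling`` inside the half-open sample ``window`` and
    zero elsewhere.  Trials use uncorrelated unit-variance innovations.
    """
    a, b = window
    if not 1 <= a < b <= samples:
        raise ValueError("window must lie inside (p, samples)")
    lower = np.array([[diag, coupling], [0.0, diag]])
    if not is_stable(lower[None]):
        raise ValueError("unstable parameter combination")
    coeffs = np.zeros((samples, 1, 2, 2))
    coeffs[:, 0, 0, 0] = diag
    coeffs[:, 0, 1, 1] = diag
    coeffs[a:b, 0, 0, 1] = coupling
    model = GroundTruthModel(
        coefficients=coeffs,
        structural_mask=np.array([[True, True], [False, True]]),
        dynamic_mask=np.array([[False, True], [False, False]]),
        regime_bounds=np.array([0, a, b, samples]),
        fs=fs,
    )
    Y = simulate_trials(model, trials, trial_corr=(0.0, 0.0), seed=seed)
    return Y, model
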