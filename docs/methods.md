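# Methods

This note documents the estimators, the simulator, the evaluation machinery
and the numerical choices made in `dynstok`. Symbols: `N` trials, `d`
channels, `T` samples, `p` model order, `Fs` sampling rate.

## 1. tvMVAR model and state layout

The time-varying multivariate autoregressive model is

    Y_t = Σ_{k=1..p} A_{k,t} Y_{t−k} + ε_t ,

per trial, with shared coefficients across trials. Trials are stacked into
the measurement equation

    z_t = H_t x_t + v_t ,

where `z_t` is the `(N × d)` matrix of current samples,
`H_t = (Y_{t−1}, …, Y_{t−p})` the `(N × d·p)` lag matrix (lag-major column
blocks, most recent first), and `x_t` the `(d·p × d)` state whose column `l`
holds the regression weights predicting channel `l`; the mapping to
coefficient matrices is `A_k[l, j] = x[(k−1)·d + j, l]`
(`state_to_coefficients` / `coefficients_to_state`, exact inverses).
Output frames at `t < p` have no full lag window and are NaN-masked;
`TvmvarEstimate.valid_from = p`.

## 2. General linear Kalman filter (KF)

Random-walk state evolution with identity transition:

* prediction: `x⁻_t = x⁺_{t−1}`, `P⁻_t = P_{t−1} + c² I`;
* innovation: `E_t = z_t − H_t x⁻_t`, `Σ_r = Eᵀ E / (N−1)`;
* adaptive measurement noise: `R̂_t = R̂_{t−1} + c (Σ_r − R̂_{t−1})`
  (the same constant `c` serves as transition variance and noise-update
  rate);
* gain: `K_t = P⁻ Hᵀ (H P⁻ Hᵀ + tr(R̂_t) I_N)⁻¹` — the trace summarizes the
  channel-noise level into a single ridge on the `(N × N)` innovation
  covariance;
* update: `x⁺_t = x⁻_t + K_t E_t`, `P_t = (I − K_t H) P⁻` symmetrized as
  `(P + Pᵀ)/2` each step.

`c` trades smoothness against tracking speed (default 0.02). When the
bracketed matrix has condition number above 1e12 the inverse falls back to a
pseudo-inverse. `tune_kf_c_rev` selects `c` on a grid by minimizing the
relative error variance

    REV = Σ_t ‖z_t − H_t x⁻_t‖² / Σ_t ‖z_t‖² ,

i.e. one-step prediction error normalized by signal power (smallest `c` wins
ties). REV is only approximately invariant to input rescaling because
`P_0 = I`, `R̂_0 = I` are fixed; the adaptive noise estimate absorbs the
scale within a few samples (~2e-5 relative on the bundled demo).

## 3. Self-tuning optimized Kalman filter (STOK)

Assuming the projected error covariance is proportional to the measurement
noise covariance, the Kalman update collapses to an exponential moving
average between the previous state and the instantaneous least-squares
solution:

    x⁺_t = (x⁺_{t−1} + c_t H̃⁺_t z_t) / (1 + c_t) .

**Damped-SVD pseudo-inverse.** `H = U S Vᵀ`; the smallest component count
`k` whose energy fractions `s_i²/Σs_j²` cumulate to ≥ θ (default 0.99) is
retained, `λ = s_{k+1}²` (0 when everything is retained), and

    H̃⁺ = V diag(s_i / (s_i² + λ)) Uᵀ .

All components are shrunk by the filter factors; factors never exceed
`1/s_i`, and numerically zero singular values (below
`s_max · max(N, d·p) · eps`) contribute nothing. `θ = 1` disables
regularization (plain pseudo-inverse).

**Self-tuned memory decay.** At each `t`, two consecutive non-overlapping
segments are formed: NEW = samples `t−p…t`, OLD = `t−2p…t−p−1` (both clipped
to samples with a full lag window, so full self-tuning starts at `t = 2p+1`;
`c_t = b` before that). One pooled least-squares model is fitted per segment
and the residual traces compared:

    c_t = min(b + |tr Σ̂_new − tr Σ̂_old| / tr Σ̂_old, 1 − b) ,   b = 0.05 .

When a model of the immediate past stops explaining incoming data — a
coefficient change inside the NEW segment — the ratio jumps and the filter
speeds up; `c_t ∈ [0.05, 0.95]` always. A per-sample variant (averaging
residuals of instantaneous regularized fits instead of pooled segment fits)
is available via `StokConfig(residual_strategy="per_sample")`; it tracks only
innovation-variance changes, not coefficient changes, and is kept as an
ablation. `fixed_c` bypasses self-tuning entirely.

The filter caches per-sample Gram (`HᵀH`) and cross (`Hᵀz`) matrices so
segment fits cost one `(d·p × d·p)` Hermitian pseudo-inverse each, rather
than repeated stacked SVDs. Diagnostics record `λ`, the retained component
count, the retained variance fraction per sample, and REV.

## 4. Spectral measures

On a frequency grid `f` (default 1–100 Hz, 1 Hz steps, clipped to Nyquist):

    Ā(f, t) = I − Σ_{k=1..p} A_{k,t} e^{−i 2π f k / Fs} .

Squared row-normalized PDC:

    π̄_lj(f, t) = |Ā_lj|² / Σ_m |Ā_lm|² ,

so each target row sums to 1 over sources (`check_pdc_row_sums` asserts the
invariant at 1e−9). Parametric PSD uses the transfer function
`B = Ā⁻¹` and a time-invariant innovation covariance `Σ̂`:

    PSD(f, t) = B Σ̂ B* ,

with `Σ̂` the element-wise median of the per-sample innovation covariance
over the last half of valid samples (discarding filter adaptation),
symmetrized. Singular `Ā` frames yield NaN with a warning. PDC is computed
in time chunks to bound memory (the `(d, d, F, T)` tensor at 40 nodes and
100 frequencies is ~0.5 GiB in float64).

## 5. Surrogate-network simulator

Emulates event-related cortical dynamics as a regime-switching reduced AR(6)
process (`TRUE_ORDER = 6`):

* **Skeleton** (drawn once): structural density ~ U(0.6, 0.8) of directed
  off-diagonal pairs; 50% of structural links carry dynamics.
* **Diagonal dynamics** (drawn once, constant across regimes): each node a
  positive AR(2) pair on lags 1–2 with magnitudes from the grid
  0.10, 0.11, …, 0.50, rejection-sampled to pole radius < 0.99.
* **Couplings** (redrawn per regime): each dynamic link a signed pair of
  halved grid magnitudes at lags `(δ, δ+1)`, delay `δ ~ U{1…5}`.
* **Regimes**: 3 quasi-stationary regimes with random boundaries, each
  ≥ 150 ms; every regime's companion matrix must have spectral radius < 1.
* **Trials**: driven by unit-variance white noise with cross-trial
  correlation (mean 0.1, sd 0.07) via a shared-component construction
  `ε_n = λ_n g + √(1−λ_n²) e_n`; burn-in of `10 p` samples discarded.

**Stabilization.** Raw coupling draws are almost never stable beyond ~10
nodes (measured acceptance 0/200 at 20–40 nodes, median companion radius
1.08–1.17), so pure rejection sampling cannot scale to the node-count sweep.
When a draw is unstable the couplings are shrunk proportionally to the
stability boundary (bisection for the largest `γ ≤ 1` with `diag + γ·off`
stable): diagonals stay on the printed grid, the connection structure and
delays are untouched, and off-diagonal magnitudes only shrink. Small
networks (≤ 10 nodes, plain acceptance ~0.57) are mostly unaffected.

**Corruption operators.** `add_observation_noise` adds white noise at a
per-channel signal-to-noise power ratio (linear by default, `units="db"`
accepted). `apply_spatial_mixing` premultiplies every sample by a
row-normalized Gaussian point-spread kernel
`M_ij ∝ exp(−|pos_i − pos_j|²/2σ²)` on a 150 × 150 mm grid.

The bivariate demonstration (`generate_bivariate_demo`) is the two-node
AR(1) benchmark: self-coefficients 0.9, coupling 2 → 1 of 0.5 active during
samples 400–600 of 1000, 200 trials, Fs = 200 Hz, uncorrelated innovations.

## 6. Evaluation

**ROC/AUC.** Ground-truth and estimated PDC tensors are pooled over all
off-diagonal `(l, j, f, t)` cells (non-finite cells dropped). The ground
truth is binarized (`> 0` by default, or above the median of its nonzero
cells), the estimate swept over 20 equally spaced quantile criteria
(1st–99th percentile), and sensitivity/specificity per criterion traced into
a ROC curve; AUC is the trapezoid area with (0,0) and (1,1) anchors.
Counting uses one sort plus binary searches over the positive/negative
pools — bit-identical to explicit per-threshold masking, ~40× cheaper at 40
nodes. `strongest_connection_subset` restricts cells to zero-truth cells
plus nonzero cells above the q-quantile of nonzero magnitudes.

**Flows and statistics.** `summed_flow` averages PDC in a band (default
40–90 Hz) and sums over targets (outflow) or sources (inflow);
`baseline_zscore` standardizes each cell against a baseline interval
(default −100–0 ms, sd with ddof = 1, zero-variance cells → NaN with
warning); `global_connectivity` averages z-scored PDC over off-diagonal
pairs; `bootstrap_difference_test` resamples subjects with replacement
(default 10 000 draws) and returns two-sided p-values floored at
`1/n_boot`. `select_model_order_fpe` fits pooled-OLS stationary models at a
common sample set for all candidate orders and minimizes
`log FPE(p) = log det Σ_ε + d [log(M + d p + 1) − log(M − d p − 1)]`.

## 7. Numerical choices

* Warm-up frames (`t < p`) are NaN, never zero: downstream consumers use
  `nanmean`/masking rather than silently biased averages.
* KF covariance symmetrization each step; pinv fallback above condition
  1e12; STOK raises on non-finite states instead of propagating NaN.
* SVD truncation tolerance `s_max · max(N, d·p) · eps`; damped factors use
  a guarded divide so exactly zero singular values map to zero gain.
* The self-tuning ratio uses pooled Gram/cross sufficient statistics; RSS is
  computed as `Σ‖z‖² − tr(x̂ᵀ Hᵀz)` and clamped at 0 against rounding.
* All seeded entry points accept integer seeds; sub-seeds are derived
  arithmetically below 2³¹ so results are bit-reproducible per platform.

## 8. Scope and limitations

* The simulator validates *detection* of directed interactions under a known
  generative model; it is not a biophysical forward model. Stabilized
  (shrunk) coupling draws mean large-network effective coupling magnitudes
  are smaller than their nominal grid values.
* FPE order selection is not consistent — its penalty vanishes with sample
  count, so it may overestimate the order at very large trial counts; treat
  it as a lower-bound heuristic and inspect the REV/FPE curve.
* REV-based tuning and the filters assume trials are exchangeable
  realizations of one underlying process; strong trial-to-trial latency
  jitter violates this and biases coefficients toward smoother dynamics.
* STOK's decay floor `b = 0.05` keeps it slightly noisier than an optimally
  tuned KF in long stationary stretches; its advantages are robustness at
  high channel counts and adaptation speed at regime changes, without
  per-dataset tuning.
* The parametric PSD assumes a time-invariant innovation covariance; strong
  nonstationarity in noise power is attributed to the coefficients.
* Spatial mixing and observation noise are applied instantaneously and
  independently per sample; no temporally correlated sensor noise is
  modeled.
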