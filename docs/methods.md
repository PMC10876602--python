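# Methods

## The model

Quiet-stance center-of-pressure (CoP) sway is modeled as the planar
superposition of two *independent* long-range-correlated components that
need not be orthogonal and need not align with the anatomical
anteroposterior (AP) / mediolateral (ML) axes. With fractional Gaussian
noise (fGn) components ε₁, ε₂ carrying Hurst exponents H₁ > H₂ and
oriented at angles θ₁, θ₂ to the x (ML) axis, the observed planar
fluctuations are

    [x⁽¹⁾]   [cos θ₁  cos θ₂] [ε₁]
    [x⁽²⁾] = [sin θ₁  sin θ₂] [ε₂].

Projecting the trajectory onto a direction θ,
x⁽ᶿ⁾ = x⁽¹⁾cos θ + x⁽²⁾sin θ = ε₁cos(θ−θ₁) + ε₂cos(θ−θ₂), annihilates
ε₁ exactly when θ = θ₁ + 90°, leaving a pure (rescaled) ε₂, and vice
versa. The direction-dependent scaling exponent α(θ) therefore attains
its minimum orthogonal to the strong-correlation component and its
maximum orthogonal to the weak one, which yields the orientation
estimates

    θ̂₁ = θ̂_min ± 90° (mod 180°),   θ̂₂ = θ̂_max ± 90° (mod 180°).

The package fixes the "+90°" branch; both branches coincide after
mod-180 reduction. Given θ̂₁, θ̂₂ the components are reconstructed with
the exact analytic inverse of the 2×2 mixing matrix (determinant
sin(θ̂₂−θ̂₁)). The per-trial summary statistic is the suborthogonality
angle Δθ ∈ (0°, 90°], the axial separation of θ̂₁ and θ̂₂; Δθ = 90°
means orthogonal control.

## Direction-dependent scaling (DDMA)

Each projected series is integrated (cumulative sum) and, for each odd
window length s, a centered Savitzky–Golay polynomial trend of degree m
is removed. The fluctuation function is the RMS residual over all
interior points with a complete window,

    F⁽ᶿ⁾(s) = sqrt( (1/(N−s+1)) Σᵢ (y[i] − ỹ_SG^{(m,s)}[i])² ),

with i running from (s+1)/2 to N−(s−1)/2 — no edge padding, which is
why even window lengths are rejected rather than rounded. F ~ s̃^α on
the *corrected* timescale s̃ = s/c(m), which aligns the DMA scale with
Fourier frequency; the correction constants are tabulated as
c(0) = 1.00 and c(2) = 1.93 (stored as named constants; the analytic
kernel derivation behind them is out of this package's scope). α is the
unweighted OLS slope of log₁₀F vs log₁₀s̃ inside the fit window.

Implementation: the Savitzky–Golay smoother is a valid-mode FIR
convolution (scipy `savgol_coeffs` + `oaconvolve`), batched across all
projection directions at once, so one full 179-angle sweep of an
n = 10 000 trajectory takes a few seconds on one core. The brute-force
per-window polynomial regression lives in the test suite as the oracle
the fast path must match to 1e−10.

## Defaults and why

- **Angle grid**: 179 directions θ_k = k·(180°/179), k = 0…178 — the
  study's grid increment of π/179 rad over [0, π). Argmin/argmax are
  taken on the grid (lowest index wins ties); no sub-grid refinement.
- **Detrending order**: m = 2 (the study's DDMA); m = 0 (classic DMA)
  is supported.
- **Fit window**: 1.2 < log₁₀s̃ < 2.5, i.e. raw windows of roughly
  31–610 samples (0.16–3.2 s at 100 Hz), strict inequalities, ≥ 3 grid
  points required.
- **Scale grid**: ~25 odd, log-spaced windows from 5 up to
  min(N/4, 611) samples. 611 is the largest odd window whose corrected
  scale stays at the top of the fit window; the N/4 ceiling keeps at
  least four windows of data at the largest scale. When the usable grid
  cannot reach the configured upper fit bound the trial record carries a
  `fit_window_truncated` flag and the fit uses the intersection.
- **Demeaning**: none. A constant offset in the projected series becomes
  a linear ramp in the profile, which degree-2 detrending removes
  exactly (a property test asserts this), so explicit centering is
  redundant for m = 2.
- **Component labelling**: after demixing, both reconstructed components
  are refitted and labels assigned so h₁ ≥ h₂, carrying the angles
  along. NaN (failed) fits sort last.
- **Degeneracy handling**: a sweep whose α(θ) range is below 0.05 is
  flagged `degenerate_anisotropy` (white-noise-like isotropy) rather
  than rejected; demixing refuses angle pairs with |sin Δ| < 1e−3,
  which is far below the grid resolution.
- **Preprocessing**: 4th-order zero-lag (forward–backward) Butterworth
  low-pass at 10 Hz, the acquisition filter of the datasets this
  pipeline targets. It is off by default for synthetic trials (they are
  band-unlimited by construction) and opt-in for real CoP tables.

## Synthetic data

`generate_fgn` uses exact circulant-embedding (Davies–Harte) spectral
synthesis; the circulant eigenvalues of the fGn autocovariance are
non-negative for all H ∈ (0, 1), with a Cholesky fallback for very
short series. Sampled series have theoretical unit variance and are
additionally standardized (zero mean, unit sample variance) before
mixing, since component amplitudes are not part of the model.

`simulate_cohort` emulates the study design this method was built for:
groups YA (27 participants), OA (22), PN (32), PM (32); a 2×2 condition
grid (eyes open/closed × stable/unstable surface); 3 trials per
condition; 3000 samples per trial (30 s at 100 Hz). Per trial the true
separation is baseline 90° plus a group offset (defaults 0 / −6 / −21 /
−19°, the magnitude ordering of the study's group contrasts), a
condition offset (−3.8° eyes closed, −6.4° unstable), a Gaussian
participant intercept (SD 4°) and trial noise (SD 4°), redrawn
(bounded retries) until it falls in (0°, 90°]; θ₁ is uniform, θ₂ placed
at the separation; H₁ ~ N(0.70, 0.05), H₂ ~ N(0.45, 0.05) with
H₁ − H₂ ≥ 0.10 enforced. All randomness derives from one master seed
through per-trial counters, so cohorts reproduce trial-by-trial.

What the generator does *not* emulate: measurement noise, filter
roll-off, nonstationary drifts, scaling crossovers (real CoP shows a
crossover near log₁₀s̃ ≈ 1.2 and per-direction exponents up to ~1.25,
i.e. fBm-like regimes, whereas the generator mixes pure fGn with
H < 1), medication state as a within-participant factor (PM is simulated
as a separate participant set although the study's PN/PM are the same
patients on/off Levodopa), and any AP/ML anatomical anchoring of θ₁.
Passing tests therefore demonstrate correct recovery of the generative
model, not the physiological claims about real sway.

Because separations are truncated at the 90° ceiling, realized group
means differ slightly from the nominal offsets near the baseline.
Parameter-recovery tests therefore compare the pipeline's fitted group
contrasts against contrasts fitted to the *recorded ground-truth*
separations under the identical model, which is the estimator-vs-latent
truth comparison the truncation leaves well-defined.

## Group statistics

The group stage fits, by REML (statsmodels MixedLM),

    Δθ ~ Group × (EyesClosed + Unstable) + H₁ + H₂ + (1 | Participant)

with YA as the baseline level. Coefficients are reported as estimate,
SE, t = B/SE and a Wald p-value under the normal approximation (the
result object names the approximation; Satterthwaite degrees of freedom
are not available in this backend). Rows flagged degenerate or with
missing metrics are excluded and counted. Constant H covariates raise
an explicit rank-deficiency error instead of a silent drop. The
two-tailed 0.05 level is reported alongside fits and never used to
filter rows. Reproducing the original study's coefficient table needs
its real trial data (external downloads); this stage is validated by
parameter recovery on simulated cohorts instead.

## Problem sizes

The worked-illustration checks use n = 10 000 samples and 20 replicate
seeds (the illustration's length is not fixed by its source; 10 000
keeps single-replicate slope noise near ±0.03). Cohort-level validation
uses the three-group study design (81 participants × 12 trials) at the
study's trial length n = 3000. White-noise calibration uses 10 seeds at
n = 10 000.

## Known limitations

- Orientation estimates are grid-quantized (step 180/179 ≈ 1.006°); no
  parabolic refinement is applied, matching the reference convention.
- The α(θ) maximum is a flatter extremum than the minimum, so θ̂₂ is
  noisier than θ̂₁ (visible in the replicate SDs).
- For rank-1 (single-component) input, α(θ) is flat because slopes are
  amplitude-invariant; such trials surface as `degenerate_anisotropy`
  rather than as a near-zero reconstructed component.
- Trials shorter than ~600 samples cannot support the default fit
  window and are flagged `short_data`.
- Δθ estimates fold at 90°, biasing near-orthogonal cohorts slightly
  downward; see the truncation note above.
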