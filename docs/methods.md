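# Methods

## Problem and model

Two methods measure the same movement as a curve on a common normalized
time grid (101 frames spanning 0–100% of the movement, both endpoints
included).  The study design is hierarchical: each of n subjects is
measured in m sessions with r replicates per session, by both methods
simultaneously.  Agreement is described by the frame-wise differences
d_ijk(t) = y_m1,ijk(t) − y_m2,ijk(t), modelled as a three-level linear
mixed model

d_ijk = Xβ + Z₁b_i + Z₂b_ij + Z₃b_ijk + ε_ijk,

with b_i ~ N(0, Ψ₁) (subject deviations), b_ij ~ N(0, Ψ₂) (session
deviations within subject), b_ijk ~ N(0, Ψ₃) (replicate deviations) and
ε_ijk ~ N(0, σ²C) with C the Toeplitz correlation matrix of a
stationary, invertible ARMA(p, q) process over frames.  All variance
components are in degrees²; ARMA coefficients are dimensionless.

The 95% functional limits of agreement are

μ_d ± k·√diag(Λ_d),  μ_d = Xβ,
Λ_d = Z₁Ψ₁Z₁' + Z₂Ψ₂Z₂' + Z₃Ψ₃Z₃' + σ²C,

with multiplier k = 2 by default (configurable; 1.96 gives the exact
Gaussian 95%).  Λ_d here is the covariance of a *single new* difference
curve — cross-curve covariance terms (shared subject or session effects
between two curves) do not enter the band's diagonal, because the band
describes one fresh paired measurement.  The band is pointwise: at each
frame it is calibrated to contain ~95% of difference values at that
frame; no simultaneous (whole-curve) coverage is claimed.

## Basis choices

**Fixed effects.**  Cubic regression splines with equally spaced inner
knots, clamped boundary knots (multiplicity degree+1).  The knot count
is selected by fitting a separate regression spline to every individual
difference curve for each candidate count (default candidates
0, 1, 3, 9, 19, 32) and taking the smallest candidate whose *minimum*
adjusted R² over curves reaches 0.95.  Adjusted R² is
1 − (RSS/(n−q))/(TSS/(n−1)) with q fitted coefficients and centered TSS.
If no candidate qualifies, the largest is used and flagged.

The default "no-intercept" dialect drops the first basis function of the
clamped system, giving n_inner + degree functions (12 for 9 inner cubic
knots).  The dropped function is the only one non-zero at t = 0, so this
dialect pins fitted curves to zero at the first frame — consistent with
range-of-motion preprocessing, which rebaselines every curve to start at
0.  The full system (rows summing to one) is available as an option.

**Random effects.**  Two routes estimate the same Λ_d:

* *B-spline + unstructured*: the fixed-effect basis reused at every
  level with a full covariance (q(q+1)/2 parameters per level; 78 at
  q = 12, 234 over three levels).  Statistically complete, expensive.
* *Eigenbasis + diagonal* (default): the sample covariance S of the
  pooled difference curves (unbiased, n−1 denominator, pointwise-mean
  centered) is eigendecomposed, S = QΛQ'; the smallest leading set of
  eigenvectors explaining ≥ 99% of total variance becomes an orthonormal
  random-effect basis shared by all three levels, with diagonal
  covariances (q parameters per level).  Centering uses the sample mean
  curve because the fixed-effect mean is unknown before the fit;
  eigenvalues below 1e-10 of the largest are treated as zero.

## Error structure

Within-curve errors are serially correlated; the default is ARMA(2,1)
with the theoretical autocorrelation function supplying the Toeplitz
correlation matrix (unit diagonal, so σ² is the marginal error
variance).  An optional automated scan fits {iid, AR1, CAR1, ARMA(1,1),
ARMA(2,1), ARMA(2,2)} and ranks them by whitened-ACF bound exceedances,
ties broken by BIC.  CAR1 is the continuous-time AR(1); on an equally
spaced grid it is an AR(1) restricted to positive correlation.

## Estimation

Restricted maximum likelihood with β profiled out by GLS:

−2ℓ_R = log|V| + log|X'V⁻¹X| + r'V⁻¹r + (N−p)log 2π,

summed over independent subject blocks.  Unconstrained
parameterization: log-Cholesky factors for unstructured covariances, log
standard deviations for diagonal ones and σ, and the
partial-autocorrelation (Durbin–Levinson) transform for ARMA
coefficients, which enforces stationarity and invertibility everywhere.

**Balanced fast path.**  For complete m × r layouts the per-subject
covariance is nested-exchangeable over curves; an orthogonal Helmert
contrast transform over replicates and sessions block-diagonalizes it
into three n_frames × n_frames blocks — W + rP₂ + mrP₁ (grand-mean
direction, the only block carrying fixed effects), W + rP₂ (session
contrasts) and W (replicate contrasts), where W = Z₃Ψ₃Z₃' + σ²C,
P₂ = Z₂Ψ₂Z₂', P₁ = Z₁Ψ₁Z₁'.  One criterion evaluation costs three small
Cholesky factorizations; the analytic gradient
(tr(PV̇) − r'V⁻¹V̇V⁻¹r, with the β̂ term vanishing by the envelope
property) reduces every per-parameter derivative to q×q contractions.
Derivatives of C with respect to the ARMA coordinates use finite
differences of the theoretical ACF.  Unbalanced data fall back to dense
per-subject blocks with numerical gradients; the two paths agree to
numerical tolerance (tested).

**Optimization.**  L-BFGS-B, memory 25, at most 2000 iterations,
relative criterion tolerance 1e-11, gradient tolerance 1e-6.  Start 1 is
moment-based: σ² from per-curve residual variance after projecting out
the fixed *and* all random-effect bases; per-level diagonal Ψ from the
between-group variances of per-curve basis coefficients; AR coefficients
from Yule–Walker on the fully projected residuals (projecting out only
the fixed basis leaves the smooth random effects in the residual, whose
near-integrated autocorrelation would start the optimizer inside a
degenerate basin).  Additional starts (default 3) jitter the
unconstrained vector; the best criterion wins.  Box bounds keep log-sds
in [−8, 8] (so boundary variance components park at ~1e-7 instead of
stalling the line search at −∞) and partial autocorrelations inside
±0.95: the restricted likelihood spikes as the AR polynomial approaches
the unit circle — a nearly integrated error process can impersonate the
smooth signal, especially when the fixed basis underfits the mean — and
the cap excludes that degenerate region.

**BLUPs.**  Standard conditional means Ψ Z'V⁻¹(y − Xβ̂) per group,
computed on the dense per-subject representation after the fit.

**Diagnostics.**  The residual ACF uses innovation (normalized)
residuals: each subject's marginal residual premultiplied by the inverse
Cholesky factor of its fitted marginal covariance.  Under a correct
model these are exactly white, so the averaged within-curve ACF with
±2/√N bounds is honestly calibrated; conditional (BLUP-subtracted)
residuals are *not* distributed σ²C even under a correct model and were
rejected for this purpose.  No per-curve re-centering is applied to
whitened residuals (re-centering a 101-point series induces the
classic −1/n ACF bias).  The residual-vs-average plot pairs conditional
residuals with between-method averages, time ignored, and reports a
straight-line slope with its standard error as a trend indicator.

## Synthetic study generator

`floa.synthetic` draws data *exactly* from the model above at the
emulated study's dimensions — 9 subjects × 2 sessions × 3 replicates ×
101 frames, 108 method curves, 54 difference curves per scenario:

* bias: a named smooth shape — default a plateau at 20° over frames
  25–75 with 12-frame cosine shoulders, the magnitude of a large
  between-system disagreement — *projected onto the stated truth basis*
  (the cubic 9-inner-knot system), so the generating mean is exactly
  representable and recovery studies are well-posed;
* per-level deviations on the same basis with diagonal covariances,
  defaults 4.0 / 1.0 / 0.5 deg² (subject / session / replicate SDs of
  2°, 1°, 0.7° — the subject level dominating, as between-athlete
  differences do);
* ARMA(2,1) noise, φ = (0.7, 0.15), θ = (0.3), marginal variance
  σ² = 0.25 deg² (0.5° SD — processed optical-capture angle jitter),
  innovations scaled so the marginal variance is exactly σ², 500-step
  burn-in.  With these settings the 99% eigenbasis of the difference
  curves keeps 15–20 vectors, the regime the fast recipe is designed
  for.

What the generator does *not* emulate: biomechanically realistic angle
waveforms, soft-tissue artefacts, non-Gaussian outliers, heteroscedastic
errors, or frame-level missingness.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to those features of real data.

For recovery studies the generator also exposes its population
eigenbasis (eigenvectors of ZZ', on which the stated random effects have
an exactly diagonal covariance), giving a known, data-independent
eigen+diagonal truth.

## Identifiability of σ² under the eigen recipe (limitation)

With the *data-estimated* eigenbasis truncated at 99% of total variance,
the kept basis spans — by construction — ~99% of everything, including
the serially correlated noise.  The replicate-level random effects can
then absorb the in-span noise, and σ̂² collapses toward the small
off-span remainder; this is the genuine REML optimum, not an optimizer
failure, and it persists across noise correlation strengths (weaker
correlation spreads noise over more directions, but the 99% rule then
keeps more of them).  Consequences: the *total* single-curve variance —
and hence the agreement band — remains well estimated, but the
decomposition into σ² versus replicate-level variance should not be
interpreted under the eigen recipe.  Parameter-recovery results in the
test suite therefore fit the generator's stated basis; the data-driven
pipeline is validated on band-level quantities (coverage, width,
bias).  A related effect: small-sample noise in the estimated
eigenvectors and diagonal-only covariances make the data-driven band
slightly anti-conservative at the frames with the least variance.

## Numerical choices and degenerate inputs

* Singular marginal covariances return −inf from the criterion (the
  optimizer treats it as a rejected step), never an exception.
* Curves must share the frame grid; unbalanced or missing curves shrink
  the affected subject blocks; unpaired curves are dropped from the
  differences with a warning.
* One subject, one session, or one replicate per session leaves the
  corresponding level unidentifiable; the design builder warns and
  proceeds.
* Constant curves make adjusted R² undefined (error), and a zero sample
  covariance has no eigenbasis (error).
* Fits are deterministic given data, configuration, and the optimizer
  seed.

## Problem sizes used by the test harnesses

Study-scale harnesses run the full 9 × 2 × 3 × 101 design.  The
parameter-recovery and coverage harness refits 20 independent
replicates (~25 s total on one core); Monte-Carlo oracles use 1e5
single-curve draws (variance diagonal), 6e4 subject-block draws
(marginal covariance), and a 1e6-step path (ARMA ACF).  The
eigen-vs-B-spline consistency check runs at 41 frames with a 3-knot
truth basis to keep the unstructured fit small.
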