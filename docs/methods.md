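# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stimulus model

Each trial presents a sequence of independent band-passed noise images
(default 26 images × 4 display frames at 85 Hz, 1,224 ms total). An image is
white Gaussian noise shaped in the Fourier domain by the square root of a
separable polar density: Rice over spatial frequency (parameterized by its
mean and SD, default 6 and 3 cycles/°; the shape/scale pair is recovered by
root-finding on the closed-form Rice moments) times a von Mises over
orientation on the doubled-angle circle (orientation is 180°-periodic, so the
signal axis is unique only mod 180°). Percent signal is the mean resultant
length of the orientation density: `|s|/100 = I₁(κ)/I₀(κ)`, inverted
numerically (Brent's method on the Bessel ratio); at |s| = 100 the
concentration is capped at κ = 2500, where the resultant length is within
2·10⁻⁴ of 1. The sign of `s` selects the angular mean: 0°/90° in the Cardinal
task, 45°/135° in the Oblique task, negative signal mapping to 0°/45°.
Frames are windowed by a circular aperture with a raised-cosine soft edge
(default width 0.25°) and rescaled so every frame has the same maximum
absolute deviation from mean luminance. The white-noise pixel distribution
and the pixel grid are not constrained by the task design; both are
configurable (tests and the acceptance script use a 64 px / 25.6 px-per-degree
desk-scale grid, which resolves the 15° orientation bins with several grid
points per band).

## Orientation energy

Twelve templates at θ = 0°, 15°, …, 165° weight the squared FFT magnitude by
the task's Rice density, gated to the strict band |θ − φ| < 7.5° (mod 180°).
The bands are disjoint and tile orientation, so the template sum reproduces
the radial weight exactly at every non-DC grid point; the DC component is
excluded because it carries mean luminance, not orientation. Orientation φ is
measured counterclockwise from the horizontal image axis, so a template's θ
matches the stimulus orientation convention. Raw energies are averaged over
frames and z-scored against the mean and SD of the frame-averaged energy
under a fresh zero-signal ensemble (default 1,000 trials; 300 at desk scale).
The reference is computed on frame-averaged trials rather than single frames
so that the standardized regressors `u` have unit variance under the
zero-signal ensemble. Raw energy is quadratic in luminance; `u` is only
comparable across datasets standardized against the same reference.

## Psychophysical-kernel model

Choice is Bernoulli with
`q_t = λ₁ + (1 − λ₁ − λ₂)·σ(w_b + Σ_θ w_θ u_tθ)`; λ₁ attaches to the
positive-choice asymptote. The weight prior is Gaussian with precision
`ridge·I + smooth·DᵀD`, where D is the **circular** second-difference
operator (165° wraps to 0°). With the default ridge 6 and smoothness 0.5 the
implied marginal variance is 0.1227 per weight and the adjacent-bin prior
correlation 0.209; a non-circular D reproduces neither. The bias prior is
Gaussian (variance 6.7) and each lapse has an independent exponential prior
(mean 0.06). Lapses are sampled on a logit scale mapped to (0, 0.5) each, so
λ₁ + λ₂ < 1 by construction; the implied truncation of the exponential prior
at 0.5 removes e⁻⁸·³ of its mass. All kernel analyses use only trials with
|s| < 20% signal (configurable).

The posterior is sampled by an in-package adaptive Hamiltonian Monte Carlo
sampler (analytic gradients; dual-averaging step-size adaptation toward 80%
acceptance; a diagonal mass matrix estimated midway through warmup; leapfrog
lengths jittered in [8, 24]; transitions with energy error above 1000 counted
as divergences and rejected). The default run keeps 1,000 samples after 500
warmup iterations and typically yields several hundred effective samples per
parameter. Chains are initialized at the posterior mode (L-BFGS).

Hyperparameter selection is by cross-validated held-out likelihood of the MAP
fit, averaged over random splits whose training fraction is uniform on
[0.5, 0.9] — a grid-search simplification of stochastic direct search over
the evidence; the defaults are the fixed prior values above.

**Transfer test.** Each task's low-signal trials are split into 20 random
folds. Within-task scores evaluate the held-out fold under the MAP kernel of
the same task's training folds; across-task scores transfer the orientation
weights from the other task's training folds — under whichever of ±w predicts
the held-out fold better, since the sign convention relating the two tasks is
arbitrary — while keeping the target task's bias and lapses. The reported
uncertainty is the SEM of the per-fold within-minus-across differences. Note
a finite-sample caveat the tests exercise explicitly: even under a shared
strategy, within-task prediction holds a small systematic edge at a few
hundred trials per task, because regularized estimates are biased toward
accuracy under their own covariate distribution; the null is recovered at
~2,500-trial sessions, which is what the shared-strategy test uses.

**Recovery battery.** Seven hypothetical strategies — both optimal
discrimination kernels, four one-sided detection kernels, and a mixed
strategy — are scaled to a common kernel norm (that of a discrimination
kernel with peak weight 0.8 on the z-scored energy scale), so every
hypothetical observer has the same decision-variable variance and performs
the task comparably well regardless of strategy shape. Choices are simulated
on ~800 low-signal trials with lapses of 0.03 and the model refitted. A
single simulated session of that size puts roughly ±0.03 of binomial noise on
the recovered-vs-true correlation, so the battery reports each kernel's mean
correlation over three independent choice simulations (the per-simulation
values are returned alongside); the acceptance script reports the minimum of
those means over the seven kernels.

## Voltage simulation and spike detection

Synthetic 30 kHz voltage is private white noise per channel plus a shared
background with per-channel gains in [0.5, 1.5]. The shared background is
pink (1/f-weighted) with an equal-variance broadband floor, optionally with
large shared biphasic transients ("hash"). A strictly sub-150 Hz shared
component would be annihilated by the 300 Hz high-pass and the median
common-average reference, leaving nothing for whitening to do; the broadband
floor and transients reproduce the phenomenon whitening exists to fix —
spuriously coincident threshold crossings across channels. Injected true
spikes are biphasic (0.6 ms, negative-first), with ground-truth trough times
returned.

Detection: zero-phase third-order Butterworth high-pass at 300 Hz, median
CAR, then two passes. Pass 1 whitens with the raw channel covariance (ZCA,
i.e. the symmetric inverse square root) and masks ±0.5 ms around 3σ
crossings; pass 2 re-estimates the covariance on the masked background,
re-whitens, and keeps negative 6σ crossings aligned to local minima, dropping
deflections beyond 20σ and resolving minima within 0.2 ms to the deeper one.
Thresholds are per channel on the whitened traces. The noise σ is a
MAD-initialized trimmed SD (the SD of samples within 5 MAD-sigmas): a plain
MAD×1.4826 underestimates the background SD by 5–26% at small channel counts
because the median CAR leaves each trace slightly non-Gaussian, which would
produce false 6σ events on pure noise; the trimmed estimator is equally
robust to spikes (they occupy the far tail) and calibrated on the actual
background.

## Response cleanup

Counts in the [150, 1200] ms window are Anscombe transformed
(`r = 2√(count + 3/8)`; the unbiased series inverse is used to go back to
expected counts). Each unit's transformed responses follow
`r_t = b + x_t·w_x + f^task(s_t) + c_t·w_c + ε_t` with Gaussian ε — the
transform's variance stabilization is what justifies the Gaussian likelihood.
Priors: a unit-variance squared-exponential GP over *wall time* on the drift
`x` (timescale 120 s, applied to actual inter-trial gaps), and unit-variance
squared-exponential GPs over percent signal (length scale 25) on the tuning
functions, with `f^A(0) = f^B(0)` enforced by sharing the zero-signal node
(across tasks the functions are conditionally independent given that shared
value). The model is fitted per unit by variational Bayes EM under the
mean-field factorization q(x)·q(f): both E-step updates are exact Gaussian
conditionals, the M-step solves a 3×3 system for (b, w_x, w_c) using the
posterior second moments and updates σ² in closed form, so the evidence lower
bound is nondecreasing by construction (asserted at tolerance 1e-6 per
iteration; a violation raises with the trace). When no cells are masked the
q(x) update runs in O(n²) via a precomputed eigendecomposition of the GP
kernel, shared across units; masked cells fall back to a dense solve.

Outliers are scored by exact Poisson surprisal,
`−log₂P(count | λ̂) − H(Poisson(λ̂))` with λ̂ the inverse-Anscombe of the
model prediction and the entropy computed by summation — a rate-invariant
score in bits. The three printed rules are applied in order (trials with
≥10% surprising units at 2 bits; units surprising on ≥10% of trials; single
cells beyond 8 bits masked), then the model is refitted, looping at most 10
times. A calibration fact the tests encode: the 2-bit threshold intrinsically
flags ≈5% of healthy Poisson cells (in the Gaussian limit the surprisal is
(z² − 1)/(2 ln 2), exceeding 2 bits at |z| > 1.94), so a clean session loses
a few percent of trials on the first pass rather than ~1%; the loop converges
once the flagged tail is gone. Cleaned responses subtract only the drift
estimate `x̂·w_x` — tuning and choice terms are left in, since downstream
statistics are about exactly those.

Unit exclusions: mean rate below 4 spikes/trial, residual Fano factor
(variance of count residuals about the model prediction over mean count)
above 2, Anscombe-scale response variance below 0.1, or grating circular
variance above 0.8 (computed on baseline-subtracted rates).

## Sensitivity, choice probability, decoder

f′ is the least-squares slope of cleaned responses on `λ_f·tanh(s/λ_f)`
(λ_f presets 30 and 60; default 30), estimated from |s| > 5.67% trials with
500 bootstrap resamples; σ and the noise covariance come exclusively from
|s| ≤ 5.67% per-level-centered residuals, so the two trial sets are disjoint
by construction. d′ = 50·f′/σ extrapolates to ±50% signal. CP pools
per-level-centered residuals over |s| ≤ 20% levels with at least 20 trials
and computes the exceedance probability of positive-choice over
negative-choice residuals with ties counted ½ (identical to the normalized
rank-sum statistic); significance is two-sided from the bootstrap CDF. The
choice decoder is LDA with Ledoit–Wolf shrinkage (lsqr solver) under
stratified K-fold cross-validation, reported next to a label-shuffle control
run through the identical pipeline.

## Errors-in-variables regression

Observed points are noisy measurements (known bootstrap SDs) of latent
coordinates tied by `ŷ = y₀ + β̂(x̂ − x₀)`, with crossed electrode/session
random effects on x̂, ŷ and β̂ and a per-point private term. All Δ terms are
non-centered (Δ = σ·η, η ~ N(0,1)) to avoid funnel pathologies; every scale
has a half-Cauchy prior of width five times the data SD on the matching axis
(slope scales: the y/x SD ratio); x₀, y₀ and β get weakly informative
Gaussian priors centered on the data (SDs five times the data SDs, slope
prior SD five times the SD ratio). The posterior is sampled by the same HMC
sampler. The headline quantity is the per-sample effective slope
β_eff = β + mean_s Δβ_s + mean_e Δβ_e; probability of direction is the
(one- or two-sided) tail fraction of β_eff, and marginal R² is the posterior
median of σ²_fixed/(σ²_fixed + σ²_random + σ²_noise) with
σ²_fixed = var[β_eff(x̂ − x₀)],
σ²_random = σ²_y,e + σ²_y,s + mean((x̂ − x₀)²)(σ²_β,s + σ²_β,e), and
σ²_noise = σ²_y,se + mean σ²_y,obs. With `include_random_effects=False` the
six group scales are pinned near zero and the model degrades to
measurement-error-only regression (also the appropriate form when every
electrode/session appears once); the R²-limit checks use this mode, and such
funnel-prone fits use a longer warmup (~2,000 iterations).

## Covariance analyses

Noise covariance uses the diagonal regularizer: sample correlations shrunk
toward the identity by λ_R = 0.6 and per-unit variances shrunk toward the
**median of the variances** by λ_σ = 0.1 (the alternative reading — median SD
squared — is dimensionally inconsistent with the printed formula), then
`C = R̂ ⊙ σ̂σ̂ᵀ`; the result is positive semidefinite for all λ_R ∈ (0, 1].
The held-out score is `−(1/2N)[Tr(C_train⁻¹C_test) + log|C_train|]` with
C_test the biased (1/n) second-moment matrix of the pre-centered held-out
residuals about zero; it equals −0.5 when both are the identity. The
switching test splits each task's low-signal residuals into 100 folds and
compares, per fold, the same held-out residuals under the same-task versus
other-task training covariance (paired folds), with a one-sided t test on the
100 switching scores. The f′-projection test resamples trials 500 times,
re-estimating f′ (high-signal trials) and C (low-signal trials) per task, and
reports unit-normalized projection variances for all four task combinations
with bootstrap tail fractions. Limited-range structure bins bootstrapped
(Δpreferred, correlation) pairs in 5° bins (Δpreferred folded to [0°, 90°]);
the per-bin SE is the SD of the per-bin mean across bootstrap repeats,
without additional adjustment for repeated electrode pairs across days. The
pool comparison keeps only pairs that are same-pool (sign f′ᵢf′ⱼ > 0) in one
task and different-pool in the other, so each pair contributes once to each
pool and the compositions are matched; Δpreferred bins default to 0–20°,
20–45°, 45–90°.

## Synthetic-data generator: what it does and does not emulate

The generator produces trial schedules (interleaved tasks, the 26-level
signal set with ≥10% zero-signal trials, 4 s trial cycles with occasional
exponential gaps of mean 8 s on 5% of trials to exercise the wall-time GP),
lapse-logistic observers, population responses from exactly the cleanup
model's class (baseline + GP drift + saturating tanh tuning tied at s = 0 +
choice coupling + structured noise: private diagonal, a limited-range
exponential decay in Δpreferred orientation, and per-task rank-one f′f′ᵀ
components), and raw voltage as described above. When integer counts are
emitted, the Poisson step *replaces* the private diagonal noise (only
correlated components are added to the rate), so the Anscombe-scale Gaussian
assumptions hold with Fano ≈ 1; adding both would double the variance and
break every Poisson-calibrated rule downstream. For every downstream fitter
there is a generator setting producing data exactly from that fitter's model
class, which is what the recovery tests rely on.

What it does not emulate: within-trial dynamics (onset transients, PSTH
shape), adaptation or learning across trials, non-Poisson count dispersion,
eye movements, reward history effects, electrode drift in waveform space, or
monkey-specific biases beyond the configurable lapse/bias parameters. Passing
tests therefore demonstrate correctness of the estimators under their assumed
generative classes and calibrated error rates under exchangeable noise — not
robustness to every failure mode of real recordings.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale, chosen so the full suite
exercises every estimator end to end: 64 px stimulus grids, 300-trial
zero-signal references, sessions of 300–2,500 trials, populations of 3–40
units, 100–500 bootstrap repeats, and HMC runs of 400–1,000 retained samples.
Every stochastic component takes an explicit seed (numpy Generator); the same
seed reproduces schedules, stimuli, samplers and bootstraps bit for bit.

## Known limitations

- The HMC sampler uses a fixed diagonal mass matrix after warmup and jittered
  trajectory lengths rather than full NUTS; hierarchical fits with strong
  funnels need the longer warmup the tests use.
- The VBEM drift posterior is per unit; a shared physiological drift appears
  as correlated per-unit estimates rather than a single population latent.
- The transfer test's finite-sample within-task edge (see above) means small
  sessions overstate strategy switching slightly; the package reports the SEM
  so users can judge the effect against it.
- CP significance uses the bootstrap CDF, which is slightly anticonservative
  at extreme CPs with few trials per level.
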