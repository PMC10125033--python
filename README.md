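# oridisc

Analysis machinery for interleaved coarse orientation-discrimination
experiments with chronic multielectrode population recordings in early visual
cortex, driven end-to-end by a synthetic-data generator so that every stage is
testable without any recorded data.

The package is for systems neuroscientists asking whether a *task switch*
(e.g. discriminate 0° vs 90° on one trial, 45° vs 135° on the next) changes
behavioral strategy and the structure of cortical population activity. It
implements, as a reusable library:

- **Stimulus synthesis** — band-pass filtered noise whose power spectrum is a
  Rice density over spatial frequency × a von Mises density over orientation;
  percent signal `s ∈ [−100, 100]` is 1 minus the circular variance of the
  orientation density, with the sign selecting the discriminandum.
- **Psychophysical-kernel inference** — a 15-parameter lapse-logistic model of
  choice, `q = λ₁ + (1 − λ₁ − λ₂)·σ(w_b + Σ_θ w_θ u_θ)`, over 12 z-scored
  orientation-energy regressors `u_θ`, fitted by Hamiltonian Monte Carlo with
  a circular ridge-plus-smoothness Gaussian prior on `w_θ` (implied variance
  ≈ 0.12 per weight, adjacent correlation ≈ 0.21), plus the within- vs
  across-task transfer test for strategy switching, a cross-session
  consistency score, and a simulated-choice recovery battery.
- **Spike preprocessing** — zero-phase 300 Hz high-pass, median common-average
  reference, two-pass ZCA whitening, 6σ threshold crossings aligned to local
  minima, artifact and duplicate rejection; counts in a [150, 1200] ms window.
- **Response cleanup** — the Anscombe transform `r = 2√(count + 3/8)`, a
  per-unit latent-drift model `r_t = b + x_t w_x + f^task(s_t) + c_t w_c + ε`
  with a 120 s squared-exponential GP prior on the drift `x`, fitted by
  variational Bayes EM; Poisson-surprisal outlier removal (2-bit / 8-bit
  rules) and the four unit-exclusion criteria; cleaned responses are
  `r − x̂·w_x`.
- **Sensitivity and choice probability** — tuning slope f′ from regression on
  `λ_f·tanh(s/λ_f)` (|s| > 5.67% trials only), `d′ = 50·f′/σ`, signed CP as a
  tie-aware exceedance probability on per-level-centered residuals with
  bootstrap significance, and a shrinkage-LDA population choice decoder.
- **Errors-in-variables mixed-effects regression** — Bayesian regression of
  one noisy quantity on another (e.g. CP on d′) with known measurement SDs
  and crossed electrode/session random intercepts and slopes, half-Cauchy
  scale priors, probability-of-direction and marginal R².
- **Noise-covariance change tests** — the diagonal regularizer
  `C = R̂ ⊙ σ̂σ̂ᵀ` (λ_R = 0.6, λ_σ = 0.1), a 100-fold cross-validated Gaussian
  log-likelihood switching test, the bootstrap f′-projection variance test
  `v_ij = f′ᵢᵀC_jf′ᵢ/‖f′ᵢ‖²`, and limited-range / decision-pool correlation
  analyses.

## Worked example

Simulate a session of 800 low-signal trials, let an ideal cardinal
discriminator choose, and recover its kernel:

```python
import numpy as np
import oridisc as od
from oridisc.schedule import DEFAULT_LEVEL_SET

low = DEFAULT_LEVEL_SET[DEFAULT_LEVEL_SET < 20]
spec = od.StimulusSpec(image_size_px=64, pixels_per_degree=25.6, n_images=26)
trials = od.gen_trial_schedule(800, seed=0, level_set=low)
energy = od.energy_for_trials(trials, spec, n_reference=300, seed=1)

observer = od.kernel_battery()[0]          # optimal cardinal discriminator
sim = od.simulate_observer_choices(trials, energy, observer, seed=2)
res = od.KernelModel.from_session(sim, energy).fit(seed=3)
print(res.summary().round(3))
```

which prints (excerpt):

```
            mean     sd  ci68_lo  ci68_hi      ess
w[0deg]   -0.623  0.145   -0.760   -0.480  456.431
w[45deg]  -0.085  0.117   -0.205    0.025  503.598
w[90deg]   0.488  0.144    0.351    0.636  648.308
w[135deg] -0.007  0.118   -0.127    0.114  471.515
w_b        0.120  0.128   -0.009    0.239  315.602
lambda1    0.030  0.013    0.018    0.042  582.796
lambda2    0.018  0.010    0.009    0.028  296.059
```

The recovered kernel is negative at 0° and positive at 90° — the signature of
a cardinal discriminator — and near zero at the oblique orientations; its
correlation with the generating kernel is 0.96. The lapse posteriors sit near
the generating rates (0.03), and the 68% credible intervals cover the truth.

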