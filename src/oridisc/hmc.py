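"""Adaptive Hamiltonian Monte Carlo with analytic gradients.

A compact HMC implementation used by the psychophysical-kernel model and the
errors-in-variables mixed-effects regression: dual-averaging step-size
adaptation toward a target acceptance rate, diagonal mass-matrix estimation
from the warmup draws, jittered leapfrog trajectory lengths, and divergence
counting (energy error above a fixed threshold).  All randomness comes from a
single numpy Generator, so runs are reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_hmc", "HMCResult", "effective_sample_size"]

_DIVERGENCE_ENERGY = 1000.0


@dataclass
class HMCResult:
    samples: np.ndarray          # (n_samples, dim)
    log_posterior: np.ndarray    # (n_samples,)
    accept_rate: float
    n_divergent: int
    step_size: float

    def ess(self) -> np.ndarray:
        return effective_sample_size(self.samples)


def effective_sample_size(samples: np.ndarray) -> np.ndarray:
    """Autocorrelation-based ESS (Geyer initial positive sequence), per dim."""
    x = np.atleast_2d(np.asarray(samples, float))
    if x.shape[0] == 1:
        x = x.T
    n, d = x.shape
    out = np.empty(d)
    for j in range(d):
        v = x[:, j] - x[:, j].mean()
        var = v @ v / n
        if var == 0:
            out[j] = float(n)
            continue
        acf = np.correlate(v, v, mode="full")[n - 1:] / (n * var)
        s, k = 0.0, 1
        while k + 1 < n:
            pair = acf[k] + acf[k + 1]
            if pair < 0:
                break
            s += pair
            k += 2
        out[j] = n / (1.0 + 2.0 * s)
    return out


def _leapfrog(q, p, grad, step, n_steps, logp_and_grad, inv_mass):
    logp, g = None, grad
    for _ in range(n_steps):
        p = p + 0.5 * step * g
        q = q + step * inv_mass * p
        logp, g = logp_and_grad(q)
        p = p + 0.5 * step * g
    return q, p, logp, g


def sample_hmc(logp_and_grad, q0: np.ndarray, n_samples: int = 1000,
               n_warmup: int = 500, seed: int = 0,
               target_accept: float = 0.8,
               n_leapfrog: tuple[int, int] = (8, 24)) -> HMCResult:
    """Draw from a log density given ``logp_and_grad(q) -> (logp, grad)``.

    Warmup adapts the step size by dual averaging and, halfway through,
    re-estimates a diagonal mass matrix from the warmup draws.  Divergent
    transitions (energy error > 1000) are counted and rejected.
    """
    rng = np.random.default_rng(seed)
    q = np.array(q0, dtype=float)
    dim = q.size
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    step = 0.1
    # Dual-averaging state (Hoffman & Gelman 2014 defaults).
    mu = np.log(10 * step)
    log_step_bar, h_bar, gamma, t0, kappa = 0.0, 0.0, 0.05, 10.0, 0.75

    total = n_warmup + n_samples
    samples = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    warm_draws = np.empty((n_warmup, dim))
    n_acc, n_div = 0, 0

    for it in range(total):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -logp + 0.5 * np.sum(inv_mass * p * p)
        n_steps = int(rng.integers(n_leapfrog[0], n_leapfrog[1] + 1))
        with np.errstate(over="ignore", invalid="ignore"):
            q_new, p_new, logp_new, grad_new = _leapfrog(
                q, p, grad, step, n_steps, logp_and_grad, inv_mass)
            if np.all(np.isfinite(q_new)) and np.isfinite(logp_new):
                h1 = -logp_new + 0.5 * np.sum(inv_mass * p_new * p_new)
                d_energy = h1 - h0
            else:
                d_energy = np.inf
        if d_energy > _DIVERGENCE_ENERGY:
            n_div += 1
        accept_prob = min(1.0, np.exp(-d_energy)) if np.isfinite(d_energy) else 0.0
        if rng.random() < accept_prob:
            q, logp, grad = q_new, logp_new, grad_new
            n_acc += 1

        if it < n_warmup:
            warm_draws[it] = q
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_step = mu - np.sqrt(m) / gamma * h_bar
            eta = m ** (-kappa)
            log_step_bar = eta * log_step + (1 - eta) * log_step_bar
            step = float(np.exp(log_step))
            if it == n_warmup // 2 and it > 20:
                var = warm_draws[n_warmup // 4: it].var(axis=0)
                inv_mass = np.maximum(var, 1e-8)
            if it == n_warmup - 1:
                step = float(np.exp(log_step_bar))
        else:
            samples[it - n_warmup] = q
            logps[it - n_warmup] = logp

    return HMCResult(samples=samples, log_posterior=logps,
                     accept_rate=n_acc / total, n_divergent=n_div,
                     step_size=step)
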