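"""Generative model of population spike-count responses.

On the variance-stabilized (Anscombe) scale, unit i's response on trial t is

    r_ti = b_i + x_t * wx_i + f_i^task(s_t) + c_t * wc_i + noise_ti

where x_t is a slow latent drift (squared-exponential Gaussian process over
wall time, default timescale 120 s), f^task is a saturating tuning function of
percent signal with f^A(0) = f^B(0), c_t the choice, and the noise covariance
is  diag(private_sd²) + limited-range term (decaying with difference in
preferred orientation) + per-task a·f′f′ᵀ.  Optionally, integer spike counts
are emitted by inverse-Anscombe + Poisson sampling so that the Anscombe-scale
modeling assumptions hold approximately on the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GroundTruthPopulation", "simulate_population_responses",
           "PopulationSample", "sq_exp_kernel"]


def sq_exp_kernel(t: np.ndarray, timescale: float, variance: float = 1.0,
                  jitter: float = 1e-8) -> np.ndarray:
    """Squared-exponential GP kernel over (wall) times ``t``."""
    d = np.subtract.outer(t, t)
    k = variance * np.exp(-0.5 * (d / timescale) ** 2)
    return k + jitter * np.eye(len(t))


@dataclass
class GroundTruthPopulation:
    """Generating parameters of a synthetic population.

    ``slope_A``/``slope_B`` are the per-unit tuning slopes at s = 0 on the
    Anscombe scale per percent signal; tuning saturates as
    f(s) = slope * tanh_scale * tanh(s / tanh_scale) so f^A(0) = f^B(0) = 0 by
    construction.  ``fpf_amplitude_per_task`` adds a rank-one f′f′ᵀ component
    (the task-specific feedback signature) to that task's noise covariance.
    """

    n_units: int
    baseline_b: np.ndarray
    slope_A: np.ndarray
    slope_B: np.ndarray
    drift_loading_wx: np.ndarray
    choice_loading_wc: np.ndarray
    private_sd: np.ndarray
    preferred_orientation: np.ndarray
    drift_timescale_s: float = 120.0
    tanh_scale: float = 30.0
    limited_range_amplitude: float = 0.0
    limited_range_decay_deg: float = 30.0
    fpf_amplitude_per_task: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("baseline_b", "slope_A", "slope_B", "drift_loading_wx",
                     "choice_loading_wc", "private_sd",
                     "preferred_orientation"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.n_units,):
                raise ValueError(f"{name} must have n_units={self.n_units} entries")
            setattr(self, name, v)
        if np.any(self.private_sd <= 0):
            raise ValueError("private_sd must be positive")

    @classmethod
    def default(cls, n_units: int = 30, seed: int = 0,
                **overrides) -> "GroundTruthPopulation":
        """A realistic default population: baselines near r = 2√(20) (≈20
        spikes/trial), heterogeneous tuning slopes, modest drift and choice
        loadings, unit private SD (Poisson-like on the Anscombe scale)."""
        rng = np.random.default_rng(seed)
        pref = rng.uniform(0.0, 180.0, n_units)
        # Tuning slope depends on preferred orientation relative to each
        # task's discriminanda: units near 90° (135°) favor +, near 0° (45°) −.
        slope_a = 0.015 * np.cos(np.radians(2 * (pref - 90.0)))
        slope_b = 0.015 * np.cos(np.radians(2 * (pref - 135.0)))
        params = dict(
            n_units=n_units,
            baseline_b=2.0 * np.sqrt(rng.uniform(10.0, 40.0, n_units)),
            slope_A=slope_a,
            slope_B=slope_b,
            drift_loading_wx=rng.normal(0.0, 0.3, n_units),
            choice_loading_wc=np.zeros(n_units),
            private_sd=np.ones(n_units),
            preferred_orientation=pref,
        )
        params.update(overrides)
        return cls(**params)

    def tuning(self, s: np.ndarray, task: np.ndarray) -> np.ndarray:
        """f^task(s) per trial and unit, shape (trials, units)."""
        s = np.asarray(s, float)[:, None]
        g = self.tanh_scale * np.tanh(s / self.tanh_scale)
        slope = np.where((np.asarray(task) == "cardinal")[:, None],
                         self.slope_A[None, :], self.slope_B[None, :])
        return g * slope

    def fprime(self, task: str) -> np.ndarray:
        """Per-unit tuning slope at s = 0 for a task (the f′ vector)."""
        return self.slope_A if task == "cardinal" else self.slope_B

    def noise_covariance(self, task: str) -> np.ndarray:
        """The trial-to-trial noise covariance implied for one task."""
        c = np.diag(self.private_sd ** 2)
        if self.limited_range_amplitude != 0:
            d = np.abs(np.subtract.outer(self.preferred_orientation,
                                         self.preferred_orientation)) % 180.0
            d = np.minimum(d, 180.0 - d)
            c = c + self.limited_range_amplitude * np.exp(
                -d / self.limited_range_decay_deg)
        a = float(self.fpf_amplitude_per_task.get(task, 0.0))
        if a != 0:
            f = self.fprime(task)
            nrm = np.linalg.norm(f)
            if nrm > 0:
                fu = f / nrm
                c = c + a * np.outer(fu, fu)
        return c


@dataclass
class PopulationSample:
    """Simulated responses plus the ground truth needed by oracle tests."""

    r: np.ndarray                    # (trials, units) Anscombe scale
    counts: np.ndarray | None        # (trials, units) integer counts or None
    true_x: np.ndarray               # (trials,) latent drift
    true_cov: dict                   # task -> (units, units) noise covariance


def simulate_population_responses(trials: pd.DataFrame,
                                  pop: GroundTruthPopulation,
                                  seed: int = 0,
                                  emit_counts: bool = False,
                                  ) -> PopulationSample:
    """Sample Anscombe-scale responses (and optionally counts) for a session.

    ``trials`` must have choices filled (±1).  Returns the response matrix
    together with the true latent drift x_t and the true per-task noise
    covariances, for parameter-recovery tests.
    """
    if np.any(~np.isin(trials["choice"].to_numpy(), (-1, 1))):
        raise ValueError("trials must have choices filled (simulate an "
                         "observer first)")
    rng = np.random.default_rng(seed)
    n, p = len(trials), pop.n_units

    kx = sq_exp_kernel(trials["wall_time_s"].to_numpy(float),
                       pop.drift_timescale_s)
    x = np.linalg.cholesky(kx) @ rng.standard_normal(n)

    covs, chols = {}, {}
    for task in ("cardinal", "oblique"):
        c = pop.noise_covariance(task)
        if emit_counts:
            # Poisson sampling supplies the private (diagonal) noise on the
            # Anscombe scale (variance ~1); only the correlated components are
            # added to the rate, so the implied Anscombe covariance is
            # C - diag(private^2) + I.
            c_draw = c - np.diag(pop.private_sd ** 2)
            covs[task] = c_draw + np.eye(p)
        else:
            c_draw = c
            covs[task] = c
        try:
            chols[task] = np.linalg.cholesky(c_draw + 1e-9 * np.eye(p))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "implied noise covariance is not positive semidefinite for "
                f"task={task!r} (limited_range_amplitude="
                f"{pop.limited_range_amplitude}, fpf_amplitude="
                f"{pop.fpf_amplitude_per_task.get(task, 0.0)})") from exc

    tasks = trials["task"].to_numpy()
    s = trials["signal_s"].to_numpy(float)
    c_t = trials["choice"].to_numpy(float)

    mean = (pop.baseline_b[None, :] + np.outer(x, pop.drift_loading_wx)
            + pop.tuning(s, tasks) + np.outer(c_t, pop.choice_loading_wc))
    noise = np.empty((n, p))
    for task in ("cardinal", "oblique"):
        m = tasks == task
        noise[m] = rng.standard_normal((int(m.sum()), p)) @ chols[task].T
    r = mean + noise

    counts = None
    if emit_counts:
        from .cleanup import inverse_anscombe, anscombe
        lam = np.maximum(inverse_anscombe(np.maximum(r, 1.3)), 0.0)
        counts = rng.poisson(lam)
        r = anscombe(counts)

    return PopulationSample(r=r, counts=counts, true_x=x, true_cov=covs)
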