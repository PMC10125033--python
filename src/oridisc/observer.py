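"""Lapse-logistic observers driven by orientation-energy kernels.

An observer is a 15-parameter generative model of choice: 12 weights on the
standardized orientation energies, a bias, and two lapse terms.  The decision
variable is z = w_b + Σ_θ w_θ u_θ, and the probability of the positive choice
is q = λ1 + (1 − λ1 − λ2)·sigmoid(z).  Lapse convention: λ1 attaches to the
positive (+1) asymptote — as z → +∞, q → 1 − λ2; as z → −∞, q → λ1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.special import expit

from .energy import TEMPLATE_THETAS_DEG, EnergyMatrix

__all__ = ["GroundTruthObserver", "simulate_observer_choices",
           "choice_probability_positive", "kernel_battery"]


@dataclass(frozen=True)
class GroundTruthObserver:
    """Generating parameters of a lapse-logistic observer."""

    w_theta: np.ndarray          # 12 weights on orientation energy
    w_b: float = 0.0             # bias
    lapse_pos: float = 0.0       # λ1: floor of q (positive-choice asymptote)
    lapse_neg: float = 0.0       # λ2: 1 - ceiling of q
    label: str = "observer"

    def __post_init__(self) -> None:
        w = np.asarray(self.w_theta, dtype=float)
        if w.shape != (12,):
            raise ValueError("w_theta must have 12 entries")
        object.__setattr__(self, "w_theta", w)
        if not (0 <= self.lapse_pos < 1 and 0 <= self.lapse_neg < 1):
            raise ValueError("lapses must be in [0, 1)")
        if self.lapse_pos + self.lapse_neg >= 1:
            raise ValueError("lapse_pos + lapse_neg must be < 1")


def choice_probability_positive(u: np.ndarray, obs: GroundTruthObserver) -> np.ndarray:
    """Per-trial probability q of the +1 choice given regressors ``u``."""
    z = obs.w_b + u @ obs.w_theta
    return obs.lapse_pos + (1.0 - obs.lapse_pos - obs.lapse_neg) * expit(z)


def simulate_observer_choices(trials: pd.DataFrame, energy: EnergyMatrix,
                              obs: GroundTruthObserver, seed: int = 0,
                              ) -> pd.DataFrame:
    """Fill the ``choice`` column of a trial table by sampling the observer.

    ``energy.u`` rows must align one-to-one with ``trials`` rows.
    """
    if len(trials) != energy.u.shape[0]:
        raise ValueError(
            f"energy rows ({energy.u.shape[0]}) do not align with "
            f"trials ({len(trials)})")
    q = choice_probability_positive(energy.u, obs)
    rng = np.random.default_rng(seed)
    out = trials.copy()
    out["choice"] = np.where(rng.random(len(trials)) < q, 1, -1)
    return out


def _vm_bump(center_deg: float, width_kappa: float = 2.0) -> np.ndarray:
    """One-sided von Mises bump over the 12 orientation bins (doubled angle)."""
    ang = np.radians(2.0 * (TEMPLATE_THETAS_DEG - center_deg))
    b = np.exp(width_kappa * (np.cos(ang) - 1.0))
    return b / np.max(b)


def kernel_battery(amplitude: float = 0.8,
                   lapse: tuple[float, float] = (0.03, 0.03),
                   ) -> list[GroundTruthObserver]:
    """The hypothetical-kernel battery used for simulated-choice recovery.

    Members: the optimal Cardinal and Oblique discrimination kernels, four
    one-sided "detection" kernels (one per discriminandum), and a
    mixed-strategy kernel that performs well on both tasks.  Every member is
    scaled to the same kernel norm — that of a discrimination kernel with
    peak weight ``amplitude`` on the z-scored energy scale — so each
    hypothetical observer has the same decision-variable variance and
    performs the task comparably well regardless of strategy shape.
    """
    th = np.radians(2.0 * TEMPLATE_THETAS_DEG)
    cardinal = -np.cos(th)                      # + at 90°, − at 0°
    oblique = -np.cos(th - np.radians(90.0))    # + at 135°, − at 45°
    mixed = cardinal + oblique
    members = [
        ("discriminate_cardinal", cardinal),
        ("discriminate_oblique", oblique),
        ("detect_0", -_vm_bump(0.0)),
        ("detect_45", -_vm_bump(45.0)),
        ("detect_90", _vm_bump(90.0)),
        ("detect_135", _vm_bump(135.0)),
        ("mixed_strategy", mixed),
    ]
    target_norm = np.linalg.norm(amplitude * cardinal / np.max(np.abs(cardinal)))
    out = []
    for label, w in members:
        w = target_norm * w / np.linalg.norm(w)
        out.append(GroundTruthObserver(w_theta=w, w_b=0.0,
                                       lapse_pos=lapse[0], lapse_neg=lapse[1],
                                       label=label))
    return out
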