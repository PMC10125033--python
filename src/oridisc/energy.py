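"""Per-trial orientation-energy regressors.

The stimulus energy at orientation θ is the squared magnitude of the frame's
2-D Fourier transform summed under a template mask M(θ): the task's Rice
spatial-frequency density as radial weight, restricted to the angular band
|θ − φ| < 7.5° (mod 180°).  Twelve templates at θ = 0°, 15°, ..., 165° tile
orientation exactly.  Raw energies S (trials × 12 × frames) are frame-averaged
and z-scored against the moments of a fresh zero-signal ensemble, yielding the
standardized regressors u (trials × 12) used by the psychophysical-kernel
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import StimulusSpec, gen_stimulus_frames, radial_weight

__all__ = [
    "TEMPLATE_THETAS_DEG",
    "build_templates",
    "compute_energy",
    "standardize_energy",
    "EnergyMatrix",
    "energy_for_trials",
]

TEMPLATE_THETAS_DEG = np.arange(0.0, 180.0, 15.0)  # 12 orientation bins
_HALFWIDTH_DEG = 7.5


def _circdist180(a: np.ndarray, b: float) -> np.ndarray:
    """Absolute orientation difference mod 180°, folded to [0°, 90°]."""
    d = np.abs(a - b) % 180.0
    return np.minimum(d, 180.0 - d)


def build_templates(spec: StimulusSpec) -> np.ndarray:
    """The 12 orientation templates on the FFT grid of ``spec``.

    Returns an array of shape (12, n, n).  Each template is the radial Rice
    weight gated by the strict angular band |θ − φ| < 7.5°; the DC component
    is excluded.  The bands are disjoint and tile orientation, so the sum of
    the 12 masks reproduces the radial weight at every non-DC grid point.
    """
    rho, phi = spec.freq_grid()
    radial = radial_weight(spec, rho)
    masks = np.empty((len(TEMPLATE_THETAS_DEG),) + rho.shape)
    for i, theta in enumerate(TEMPLATE_THETAS_DEG):
        band = _circdist180(phi, theta) < _HALFWIDTH_DEG
        masks[i] = radial * band
    # Resolution check: every band must contain grid points with weight.
    if np.any(masks.reshape(len(TEMPLATE_THETAS_DEG), -1).sum(axis=1) <= 0):
        raise ValueError("FFT grid too coarse to resolve 15-degree bins")
    return masks


def compute_energy(frames: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Raw orientation energy S for one trial.

    ``frames`` is (n_frames, n, n) of luminance deviations (aperture already
    applied, as shown to the observer).  Returns (12, n_frames) of
    S_θf = Σ_ρφ |FFT(frame)|² M(θ).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if not np.all(np.isfinite(frames)):
        raise ValueError("frames contain non-finite pixels")
    power = np.abs(np.fft.fft2(frames, axes=(-2, -1))) ** 2  # (F, n, n)
    return np.einsum("tij,fij->tf", templates, power)


@dataclass
class EnergyMatrix:
    """Raw and standardized orientation-energy regressors.

    Attributes
    ----------
    S : (trials, 12, n_frames) raw energies.
    u : (trials, 12) standardized frame-averaged energies.
    reference_mean, reference_sd : (12,) moments of the frame-averaged energy
        under the zero-signal ensemble used for z-scoring.
    """

    S: np.ndarray
    u: np.ndarray
    reference_mean: np.ndarray
    reference_sd: np.ndarray


def zero_signal_reference(spec: StimulusSpec, templates: np.ndarray,
                          n_reference: int = 1000, seed: int = 0,
                          task: str = "cardinal") -> tuple[np.ndarray, np.ndarray]:
    """Per-orientation mean and SD of frame-averaged energy at zero signal.

    Moments are taken over ``n_reference`` fresh zero-signal trials (each of
    ``spec.n_images`` frames) so that the z-scored regressors have unit SD per
    orientation under the zero-signal ensemble.
    """
    if n_reference < 200:
        raise ValueError("n_reference must be >= 200 for stable moments")
    rng = np.random.default_rng(seed)
    vals = np.empty((n_reference, len(TEMPLATE_THETAS_DEG)))
    for t in range(n_reference):
        frames = gen_stimulus_frames(spec, task, 0.0,
                                     seed=int(rng.integers(2**31 - 1)))
        vals[t] = compute_energy(frames, templates).mean(axis=1)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate zero-signal reference (sd = 0)")
    return mean, sd


def standardize_energy(raw_S: np.ndarray, spec: StimulusSpec,
                       n_reference: int = 1000, seed: int = 0,
                       reference: tuple[np.ndarray, np.ndarray] | None = None,
                       ) -> EnergyMatrix:
    """Standardize raw energies against the zero-signal ensemble.

    ``raw_S`` is (trials, 12, n_frames).  The frame-averaged energy is
    z-scored per orientation with reference moments estimated from fresh
    zero-signal simulations (or supplied via ``reference``).  Raw S scales
    quadratically with luminance, so u is only comparable across datasets
    whose reference was computed under the same stimulus spec.
    """
    raw_S = np.asarray(raw_S, dtype=float)
    if raw_S.ndim == 2:
        raw_S = raw_S[:, :, None]
    templates = build_templates(spec)
    if reference is None:
        reference = zero_signal_reference(spec, templates, n_reference, seed)
    mean, sd = reference
    u = (raw_S.mean(axis=2) - mean) / sd
    return EnergyMatrix(S=raw_S, u=u, reference_mean=np.asarray(mean),
                        reference_sd=np.asarray(sd))


def energy_for_trials(trials, spec: StimulusSpec,
                      n_reference: int = 1000, seed: int = 0,
                      reference: tuple[np.ndarray, np.ndarray] | None = None,
                      ) -> EnergyMatrix:
    """Synthesize stimuli for every row of a trial table and standardize.

    Each trial's frames are regenerated from its ``noise_seed`` (frozen
    noise), energies computed under the 12 templates, and standardized.
    """
    templates = build_templates(spec)
    S = np.empty((len(trials), len(TEMPLATE_THETAS_DEG), spec.n_images))
    for k, row in enumerate(trials.itertuples(index=False)):
        frames = gen_stimulus_frames(spec, row.task, row.signal_s,
                                     seed=int(row.noise_seed))
        S[k] = compute_energy(frames, templates)
    return standardize_energy(S, spec, n_reference=n_reference, seed=seed,
                              reference=reference)
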