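"""Band-pass filtered noise stimuli for coarse orientation discrimination.

Stimuli are white-noise images shaped in the Fourier domain by a separable
polar mask: a Rice density over spatial frequency (radial coordinate) times a
von Mises density over orientation (angular coordinate, 180°-periodic).  The
von Mises concentration κ controls the orientation bandwidth and therefore the
signal strength: signal is defined as 1 minus the circular variance of the
orientation density, i.e. the mean resultant length on the doubled-angle
circle, expressed in percent.  The sign of the signal selects which of the two
task discriminanda is the angular mean (Cardinal task: 0° vs 90°; Oblique
task: 45° vs 135°, negative sign = 0°/45°).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import i0e, i1e

__all__ = [
    "StimulusSpec",
    "signal_to_kappa",
    "kappa_to_signal",
    "rice_params_from_mean_sd",
    "gen_stimulus_frames",
    "soft_aperture",
    "TASK_MEANS_DEG",
    "KAPPA_CAP",
]

# Angular mean of the von Mises mask per (task, sign of signal), in degrees of
# orientation.  Positive signal is 90° (Cardinal) or 135° (Oblique).
TASK_MEANS_DEG = {
    ("cardinal", +1): 90.0,
    ("cardinal", -1): 0.0,
    ("oblique", +1): 135.0,
    ("oblique", -1): 45.0,
}

# Finite cap on the von Mises concentration at |s| = 100% (pure-grating
# limit).  At κ = 2500 the mean resultant length is 0.9998, i.e. within the
# printed precision of the signal scale.
KAPPA_CAP = 2500.0


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and spectral statistics of the band-passed noise stimulus.

    Defaults follow the near-foveal configuration: 2.5° aperture, Rice
    spatial-frequency density with mean 6 cycles/° and SD 3 cycles/°, 26
    images of 4 frames each on an 85 Hz display (1,224 ms total).
    """

    image_size_px: int = 96
    pixels_per_degree: float = 32.0
    aperture_diameter_deg: float = 2.5
    soft_edge_width_deg: float = 0.25
    mu_rho: float = 6.0
    sigma_rho: float = 3.0
    n_images: int = 26
    frames_per_image: int = 4
    refresh_hz: float = 85.0
    max_luminance_dev: float = 1.0

    def __post_init__(self) -> None:
        if self.image_size_px < 4:
            raise ValueError("image_size_px must be at least 4")
        if self.mu_rho <= 0 or self.sigma_rho <= 0:
            raise ValueError("Rice mean and SD must be positive")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")

    @property
    def duration_ms(self) -> float:
        """Total stimulus duration: n_images * frames_per_image / refresh_hz."""
        return 1000.0 * self.n_images * self.frames_per_image / self.refresh_hz

    @property
    def field_deg(self) -> float:
        return self.image_size_px / self.pixels_per_degree

    def freq_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(rho, phi) polar coordinates of the FFT grid.

        rho in cycles/degree; phi the *stimulus* orientation in degrees —
        the orientation of the grating stripes, counterclockwise from the
        horizontal image axis, mod 180°.  Stripes run perpendicular to the
        frequency vector, so phi is the frequency-vector angle plus 90°;
        with this convention a template at θ matches a grating whose visible
        orientation is θ.
        """
        f = np.fft.fftfreq(self.image_size_px, d=1.0 / self.pixels_per_degree)
        fx, fy = np.meshgrid(f, f, indexing="xy")
        rho = np.hypot(fx, fy)
        phi = (np.degrees(np.arctan2(fy, fx)) + 90.0) % 180.0
        return rho, phi


def kappa_to_signal(kappa: float | np.ndarray) -> float | np.ndarray:
    """Percent signal implied by a von Mises concentration on the doubled-angle
    circle: 100 times the mean resultant length I1(κ)/I0(κ)."""
    kappa = np.asarray(kappa, dtype=float)
    out = 100.0 * i1e(kappa) / i0e(kappa)
    return float(out) if out.ndim == 0 else out


def signal_to_kappa(signal_s: float) -> float:
    """Concentration κ whose mean resultant length equals ``|signal_s|/100``.

    The map is the monotone inverse of the Bessel ratio I1/I0.  At
    ``|signal_s| = 100`` (a pure grating, κ → ∞) a documented finite cap
    :data:`KAPPA_CAP` is returned.
    """
    a = abs(float(signal_s))
    if a > 100.0:
        raise ValueError(f"|signal_s| must be <= 100, got {signal_s}")
    if a == 0.0:
        return 0.0
    if a >= 100.0:
        return KAPPA_CAP
    target = a / 100.0
    # I1/I0 is monotone increasing from 0 to 1; bracket then solve.
    lo, hi = 1e-12, 2.0
    while i1e(hi) / i0e(hi) < target:
        hi *= 2.0
        if hi > KAPPA_CAP:
            return KAPPA_CAP
    return float(optimize.brentq(lambda k: i1e(k) / i0e(k) - target, lo, hi,
                                 xtol=1e-12, rtol=1e-14))


def rice_params_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Solve for scipy's Rice (shape ``b``, ``scale``) matching a given mean/SD.

    The distribution is parameterized in the task by its mean and SD only; the
    (b, scale) pair is recovered by root-finding on the closed-form Rice
    moments.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("Rice mean and SD must be positive")

    def resid(p):
        b, s = np.exp(p)
        m, v = stats.rice.stats(b, scale=s, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(resid, [0.0, np.log(sd)], tol=1e-12)
    if not sol.success:  # pragma: no cover - well-conditioned for sane inputs
        raise RuntimeError(f"Rice moment matching failed: {sol.message}")
    b, s = np.exp(sol.x)
    return float(b), float(s)


def radial_weight(spec: StimulusSpec, rho: np.ndarray) -> np.ndarray:
    """Rice density over spatial frequency, evaluated on the FFT grid.

    The DC component (rho = 0) is set to zero: it carries mean luminance, not
    orientation content.
    """
    b, scale = rice_params_from_mean_sd(spec.mu_rho, spec.sigma_rho)
    w = stats.rice.pdf(rho, b, scale=scale)
    w[rho == 0] = 0.0
    return w


def angular_weight(phi_deg: np.ndarray, mean_deg: float, kappa: float) -> np.ndarray:
    """von Mises density over orientation on the doubled-angle circle."""
    ang = np.radians(2.0 * (phi_deg - mean_deg))
    # exp(kappa*(cos-1)) * scaled Bessel keeps this finite up to KAPPA_CAP.
    return np.exp(kappa * (np.cos(ang) - 1.0)) / (2.0 * np.pi * i0e(kappa))


def soft_aperture(spec: StimulusSpec) -> np.ndarray:
    """Circular aperture with a raised-cosine soft edge.

    The window is 1 inside ``aperture_diameter_deg`` minus the edge, ramps to
    0 over ``soft_edge_width_deg``, and is 0 outside.
    """
    n = spec.image_size_px
    ax = (np.arange(n) - (n - 1) / 2.0) / spec.pixels_per_degree
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    r = np.hypot(xx, yy)
    r_out = spec.aperture_diameter_deg / 2.0
    w = spec.soft_edge_width_deg
    r_in = max(r_out - w, 0.0)
    win = np.zeros_like(r)
    win[r <= r_in] = 1.0
    if w > 0:
        ramp = (r > r_in) & (r < r_out)
        win[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - r_in) / (r_out - r_in)))
    return win


def gen_stimulus_frames(spec: StimulusSpec, task: str, signal_s: float,
                        seed: int) -> np.ndarray:
    """Generate the stack of ``n_images`` luminance frames for one trial.

    Each image is white Gaussian noise multiplied in the Fourier domain by
    Rice(ρ) × vonMises(φ; task mean, κ(|signal_s|)), inverse-transformed,
    windowed by the soft-edged aperture, and rescaled so every frame has the
    same maximum absolute deviation from the mean (zero) luminance.

    Returns an array of shape ``(n_images, image_size_px, image_size_px)``;
    frames are zero-mean luminance deviations.  A fixed ``seed`` freezes the
    noise (same seed, same pixels).
    """
    if task not in ("cardinal", "oblique"):
        raise ValueError(f"unknown task {task!r}")
    s = float(signal_s)
    if abs(s) > 100.0:
        raise ValueError("|signal_s| must be <= 100")
    kappa = signal_to_kappa(s)
    sign = 1 if s >= 0 else -1
    mean_deg = TASK_MEANS_DEG[(task, sign)]

    rho, phi = spec.freq_grid()
    # The *power* spectrum follows Rice x vonMises, so the amplitude mask is
    # the square root of the density product.
    mask = np.sqrt(radial_weight(spec, rho) * angular_weight(phi, mean_deg, kappa))
    window = soft_aperture(spec)

    rng = np.random.default_rng(seed)
    n = spec.image_size_px
    frames = np.empty((spec.n_images, n, n))
    for k in range(spec.n_images):
        noise = rng.standard_normal((n, n))
        shaped = np.fft.ifft2(np.fft.fft2(noise) * mask).real
        img = shaped * window
        peak = np.max(np.abs(img))
        if peak == 0:  # pragma: no cover - degenerate mask
            frames[k] = img
        else:
            frames[k] = img * (spec.max_luminance_dev / peak)
    return frames
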