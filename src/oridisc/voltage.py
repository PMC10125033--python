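"""Synthetic multichannel raw voltage for exercising spike detection.

Each channel is private white Gaussian noise plus a shared background —
pink (low-frequency dominated) with a broadband floor, seen through random
per-channel gains, optionally with shared biphasic transients — emulating the
highly correlated background fluctuations across chronically implanted
electrodes.  Biphasic spike templates are injected at Poisson times and the
ground-truth times returned, so detection performance can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["VoltageSnippet", "simulate_voltage", "biphasic_template",
           "SAMPLING_RATE_HZ"]

SAMPLING_RATE_HZ = 30_000


@dataclass
class VoltageSnippet:
    """channels × samples voltage at 30 kHz with known injected spike times."""

    data: np.ndarray                      # (channels, samples)
    true_spike_times: list                # per-channel arrays of sample indices
    shared_background_sd: float
    fs: int = SAMPLING_RATE_HZ


def biphasic_template(fs: int = SAMPLING_RATE_HZ, width_ms: float = 0.6,
                      amplitude: float = 8.0) -> np.ndarray:
    """A canonical biphasic (negative-first) spike waveform.

    ``amplitude`` is the depth of the negative trough in units of the private
    noise SD (which is 1 in the simulator).
    """
    n = int(round(width_ms * 1e-3 * fs))
    t = np.linspace(-2.5, 2.5, n)
    w = -t * np.exp(-t ** 2)          # derivative-of-Gaussian biphasic shape
    w = w / np.min(w) * -1.0          # trough at -1
    return amplitude * w


def simulate_voltage(n_channels: int, duration_s: float,
                     shared_background_sd: float = 0.0,
                     spike_rate_hz: float = 0.0, seed: int = 0,
                     spike_amplitude: float = 8.0,
                     shared_transient_rate_hz: float = 0.0) -> VoltageSnippet:
    """Simulate a multichannel 30 kHz voltage snippet.

    Parameters
    ----------
    shared_background_sd : float
        SD of the pink (low-frequency dominated) background common to all
        channels, relative to the private noise SD of 1.  Channels see it
        through random gains in [0.5, 1.5].
    spike_rate_hz : float
        Poisson rate of injected biphasic spikes per channel.
    shared_transient_rate_hz : float
        Poisson rate of large biphasic deflections shared across channels
        (broadband background "hash"); their trough depth is 8x
        ``shared_background_sd``.  These are what produce spurious coincident
        threshold crossings when the channels are not whitened.
    """
    if duration_s > 120:
        raise ValueError("duration_s capped at 120 s (desk scale)")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    fs = SAMPLING_RATE_HZ
    n = int(round(duration_s * fs))

    data = rng.standard_normal((n_channels, n))
    if shared_background_sd > 0:
        # Shared background: low-frequency dominated (pink) but with a
        # broadband floor, as the correlated hash across nearby electrodes is
        # in practice; per-channel gains keep a median CAR from cancelling it
        # exactly, which is what the ZCA whitening is for.
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        f[0] = f[1]
        pink = np.fft.irfft(spec / np.sqrt(f), n)
        pink /= pink.std()
        shared = np.sqrt(0.5) * (pink + rng.standard_normal(n))
        shared *= shared_background_sd / shared.std()
        gains = rng.uniform(0.5, 1.5, n_channels)
        data += gains[:, None] * shared[None, :]
        if shared_transient_rate_hz > 0:
            tmpl = biphasic_template(fs, amplitude=8.0 * shared_background_sd)
            n_tr = rng.poisson(shared_transient_rate_hz * duration_s)
            starts = rng.integers(0, n - len(tmpl), size=n_tr)
            for t0 in starts:
                data[:, t0:t0 + len(tmpl)] += gains[:, None] * tmpl[None, :]

    template = biphasic_template(fs, amplitude=spike_amplitude)
    half = len(template) // 2
    true_times: list = []
    for ch in range(n_channels):
        if spike_rate_hz > 0:
            n_spk = rng.poisson(spike_rate_hz * duration_s)
            times = np.sort(rng.integers(half, n - half - len(template),
                                         size=n_spk))
        else:
            times = np.array([], dtype=int)
        for t0 in times:
            data[ch, t0:t0 + len(template)] += template
        # Record the trough sample (detection aligns to the local minimum).
        trough = int(np.argmin(template))
        true_times.append(times + trough)
    return VoltageSnippet(data=data, true_spike_times=true_times,
                          shared_background_sd=shared_background_sd, fs=fs)
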