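"""Trial schedules for interleaved two-task sessions.

A session is a pandas DataFrame (the trial table) with one row per trial:
task label, percent signal, wall time, noise seed, choice and validity flags.
Signal levels are drawn from a fixed set of 26 amplitudes spanning 0-97%,
with zero-signal (ambiguous) trials guaranteed at least a configurable
fraction of the schedule.  Trials are nominally 4 s apart with occasional
longer gaps so that downstream drift models see realistic wall-time structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_LEVEL_SET", "TRIAL_TABLE_COLUMNS", "gen_trial_schedule"]

# 26 signal amplitudes from 0% (ambiguous) to 97% (near-pure gratings),
# geometrically spaced over the informative range as in staircase practice.
DEFAULT_LEVEL_SET: np.ndarray = np.concatenate(
    [[0.0], np.round(97.0 * (97.0 / 3.0) ** (np.arange(25) / 24.0 - 1.0), 2)]
)

TRIAL_TABLE_COLUMNS = [
    "trial_id", "session_id", "wall_time_s", "task", "signal_s",
    "noise_seed", "choice", "valid_behavior", "valid_neural",
]

_TRIAL_PERIOD_S = 4.0       # complete trial cycle duration
_GAP_FRACTION = 0.05        # fraction of trials followed by an extra gap
_GAP_MEAN_S = 8.0           # mean of the exponential extra gap


def gen_trial_schedule(n_trials: int, session_id: str = "S0", *,
                       interleaved: bool = True, task: str = "cardinal",
                       level_set=None, zero_fraction: float = 0.1,
                       seed: int = 0) -> pd.DataFrame:
    """Generate a trial table for one session.

    Parameters
    ----------
    n_trials : int
        Number of completed trials (>= 1).
    interleaved : bool
        If True, the task is assigned per trial uniformly at random; otherwise
        every trial uses ``task``.
    level_set : array-like, optional
        Unsigned signal amplitudes to sample from (default: the 26-level set).
        A random sign is attached to each nonzero level.
    zero_fraction : float in [0, 1]
        Minimum fraction of zero-signal trials.
    seed : int
        Seeds all randomness; the same seed reproduces the table exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError("zero_fraction must be in [0, 1]")
    levels = DEFAULT_LEVEL_SET if level_set is None else np.asarray(level_set, float)
    if levels.size == 0:
        raise ValueError("level_set must be nonempty")

    rng = np.random.default_rng(seed)
    tasks = (rng.choice(["cardinal", "oblique"], size=n_trials)
             if interleaved else np.full(n_trials, task))

    n_zero = int(np.ceil(zero_fraction * n_trials))
    amp = rng.choice(levels, size=n_trials)
    zero_idx = rng.choice(n_trials, size=min(n_zero, n_trials), replace=False)
    amp[zero_idx] = 0.0
    sign = rng.choice([-1.0, 1.0], size=n_trials)
    signal = amp * sign

    gaps = np.full(n_trials, _TRIAL_PERIOD_S)
    extra = rng.random(n_trials) < _GAP_FRACTION
    gaps[extra] += rng.exponential(_GAP_MEAN_S, size=int(extra.sum()))
    wall = np.cumsum(gaps) - gaps[0]

    return pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "session_id": session_id,
        "wall_time_s": wall,
        "task": tasks,
        "signal_s": signal,
        "noise_seed": rng.integers(0, 2**31 - 1, size=n_trials),
        "choice": np.zeros(n_trials, dtype=int),  # 0 = not yet simulated
        "valid_behavior": np.ones(n_trials, dtype=bool),
        "valid_neural": np.ones(n_trials, dtype=bool),
    })
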