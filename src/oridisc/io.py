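"""HDF5 / CSV persistence for the pipeline's standard objects."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .energy import EnergyMatrix
from .schedule import TRIAL_TABLE_COLUMNS

__all__ = ["save_trials", "load_trials", "save_frames", "load_frames",
           "save_energy", "load_energy", "save_responses", "load_responses",
           "save_kernel_posterior"]


def save_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=[c for c in TRIAL_TABLE_COLUMNS
                                              if c in trials.columns])


def load_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_frames(frames: np.ndarray, path, trial_id: int = 0) -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group("frames")
        name = f"trial_{trial_id}"
        if name in grp:
            del grp[name]
        grp.create_dataset(name, data=frames)


def load_frames(path, trial_id: int = 0) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[f"frames/trial_{trial_id}"][()]


def save_energy(energy: EnergyMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("energy")
        grp.create_dataset("S", data=energy.S)
        grp.create_dataset("u", data=energy.u)
        ref = grp.create_group("reference")
        ref.create_dataset("mean", data=energy.reference_mean)
        ref.create_dataset("sd", data=energy.reference_sd)


def load_energy(path) -> EnergyMatrix:
    with h5py.File(path, "r") as f:
        return EnergyMatrix(S=f["energy/S"][()], u=f["energy/u"][()],
                            reference_mean=f["energy/reference/mean"][()],
                            reference_sd=f["energy/reference/sd"][()])


def save_responses(r: np.ndarray, path, truth: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=r)
        if truth:
            grp = f.create_group("truth")
            for k, v in truth.items():
                grp.create_dataset(k, data=np.asarray(v))


def load_responses(path):
    with h5py.File(path, "r") as f:
        r = f["responses"][()]
        truth = ({k: f["truth"][k][()] for k in f["truth"]}
                 if "truth" in f else None)
    return r, truth


def save_kernel_posterior(results, h5_path, json_path=None) -> None:
    """Posterior samples to HDF5 plus a JSON summary (mean, 68% CI)."""
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("samples", data=results.samples)
        f.attrs["n_divergent"] = results.n_divergent
        f.attrs["accept_rate"] = results.accept_rate
    if json_path is not None:
        lo, hi = results.credible_interval(0.68)
        with open(json_path, "w") as fh:
            json.dump({"posterior_mean": results.posterior_mean.tolist(),
                       "ci68_lo": lo.tolist(), "ci68_hi": hi.tolist()}, fh,
                      indent=1)
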