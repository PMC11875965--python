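"""Serialization helpers: policy weights, kinematics CSV, raw EMG CSV and
package configuration files (YAML or JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .activation import ActivationConstants, CHANNELS
from .model import DynamicsConfig, KinematicsEstimate
from .networks import ActorNetwork
from .rl import DdpgHyperparams
from .sa import SaConfig

__all__ = [
    "save_policy",
    "load_policy",
    "save_kinematics_csv",
    "load_kinematics_csv",
    "load_raw_emg_csv",
    "save_raw_emg_csv",
    "load_config",
]


def save_policy(actor: ActorNetwork, path) -> None:
    """Write actor weights as layer-name -> matrix (HDF5 for .h5/.hdf5,
    otherwise JSON)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            for name, w in actor.weights.items():
                fh.create_dataset(name, data=w)
    else:
        with open(path, "w") as fh:
            json.dump({k: w.tolist() for k, w in actor.weights.items()}, fh)


def load_policy(path) -> ActorNetwork:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return ActorNetwork(fh["W1"][()], fh["W2"][()])
    with open(path) as fh:
        d = json.load(fh)
    return ActorNetwork(np.array(d["W1"]), np.array(d["W2"]))


def save_kinematics_csv(est: KinematicsEstimate, path) -> None:
    t = np.arange(est.n_samples) / est.fs
    pd.DataFrame({"time_s": t, "wrist_deg": est.wrist_deg,
                  "mcp_deg": est.mcp_deg}).to_csv(path, index=False,
                                                  float_format="%.6g")


def load_kinematics_csv(path) -> KinematicsEstimate:
    df = pd.read_csv(path)
    return KinematicsEstimate(wrist_deg=df["wrist_deg"].to_numpy(),
                              mcp_deg=df["mcp_deg"].to_numpy())


def save_raw_emg_csv(raw: np.ndarray, path, fs: float = 1000.0) -> None:
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    t = np.arange(raw.shape[0]) / fs
    cols = {"time_s": t}
    for i, c in enumerate(CHANNELS):
        cols[c] = raw[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def load_raw_emg_csv(path) -> np.ndarray:
    """Raw multi-channel EMG from CSV (columns time_s, ecrl, edc, fcr, fds;
    strictly increasing times)."""
    df = pd.read_csv(path)
    missing = {"time_s", *CHANNELS} - set(df.columns)
    if missing:
        raise ValueError(f"raw EMG CSV missing columns: {sorted(missing)}")
    if np.any(np.diff(df["time_s"].to_numpy()) <= 0):
        raise ValueError("time_s must be strictly increasing")
    return df[list(CHANNELS)].to_numpy()


def load_config(path) -> dict:
    """Load a configuration file and build the typed config objects.

    Recognized top-level keys: ``activation``, ``dynamics``, ``ddpg``, ``sa``;
    absent sections fall back to defaults.
    """
    path = Path(path)
    with open(path) as fh:
        raw = (json.load(fh) if path.suffix == ".json"
               else yaml.safe_load(fh)) or {}
    return {
        "activation": ActivationConstants.from_dict(raw.get("activation", {})),
        "dynamics": DynamicsConfig.from_dict(raw.get("dynamics", {})),
        "ddpg": DdpgHyperparams.from_dict(raw.get("ddpg", {})),
        "sa": SaConfig.from_dict(raw.get("sa", {})),
    }
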