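"""Data-cycle container and on-disk formats.

A *data cycle* is one 10-second recording: 4-channel normalized EMG envelope
at 100 Hz synchronized with measured wrist and MCP joint angles in degrees.
Cycles are stored as plain CSV with columns
``time_s, ecrl, edc, fcr, fds, wrist_deg, mcp_deg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation import CHANNELS, EmgEnvelope
from .model import MCP_LIMITS, WRIST_LIMITS

__all__ = ["DataCycle", "load_cycle_csv", "save_cycle_csv"]

CYCLE_COLUMNS = ("time_s", *CHANNELS, "wrist_deg", "mcp_deg")


@dataclass
class DataCycle:
    """One synchronized EMG + kinematics recording.

    ``emg`` has shape ``(n, 4)`` (channels in :data:`emgmm.activation.CHANNELS`
    order); angle series are in degrees, flexion positive. ``noiseless_wrist``
    / ``noiseless_mcp`` optionally carry the pre-noise ground truth when the
    cycle was generated synthetically.
    """

    emg: np.ndarray
    wrist_deg: np.ndarray
    mcp_deg: np.ndarray
    fs: float = 100.0
    noiseless_wrist: np.ndarray | None = None
    noiseless_mcp: np.ndarray | None = None
    _keypoints: np.ndarray | None = field(default=None, repr=False, compare=False)
    _act_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.wrist_deg = np.asarray(self.wrist_deg, dtype=float)
        self.mcp_deg = np.asarray(self.mcp_deg, dtype=float)
        n = self.emg.shape[0]
        if self.emg.ndim != 2 or self.emg.shape[1] != len(CHANNELS):
            raise ValueError("emg must have shape (n, 4)")
        if self.wrist_deg.shape != (n,) or self.mcp_deg.shape != (n,):
            raise ValueError("angle series must match the EMG length")
        if np.any(self.emg < 0):
            raise ValueError("EMG envelope samples must be non-negative")
        eps = 1e-9
        if np.any(self.wrist_deg < WRIST_LIMITS[0] - eps) or np.any(
                self.wrist_deg > WRIST_LIMITS[1] + eps):
            raise ValueError("wrist angles outside joint limits")
        if np.any(self.mcp_deg < MCP_LIMITS[0] - eps) or np.any(
                self.mcp_deg > MCP_LIMITS[1] + eps):
            raise ValueError("MCP angles outside joint limits")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def envelope(self) -> EmgEnvelope:
        return EmgEnvelope(self.emg, fs=self.fs)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        cols = {"time_s": t}
        for i, c in enumerate(CHANNELS):
            cols[c] = self.emg[:, i]
        cols["wrist_deg"] = self.wrist_deg
        cols["mcp_deg"] = self.mcp_deg
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float = 100.0) -> "DataCycle":
        missing = set(CYCLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cycle CSV missing columns: {sorted(missing)}")
        t = df["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        return cls(
            emg=df[list(CHANNELS)].to_numpy(),
            wrist_deg=df["wrist_deg"].to_numpy(),
            mcp_deg=df["mcp_deg"].to_numpy(),
            fs=fs,
        )


def save_cycle_csv(cycle: DataCycle, path) -> None:
    cycle.to_frame().to_csv(path, index=False, float_format="%.6g")


def load_cycle_csv(path) -> DataCycle:
    return DataCycle.from_frame(pd.read_csv(path))
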