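"""Synthetic subjects and data cycles.

No public recordings accompany this problem, so the test harness generates
its own: a synthetic subject is a ground-truth parameter set drawn around the
generic model, and each of its 10-second data cycles mimics the recording
protocol — one wrist extension/flexion followed by one MCP extension/flexion,
driven by smooth raised-cosine excitation bursts of the four muscles (ECRL,
then FCR, then EDC, then FDS). The "measured" kinematics are produced by the
musculoskeletal model itself from the subject's true parameters, plus
Gaussian angle noise, so perfect parameter recovery is achievable in
principle and every pipeline stage is testable end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .activation import ActivationConstants, CHANNELS, EmgEnvelope
from .data import DataCycle, save_cycle_csv
from .model import (
    MCP_LIMITS,
    WRIST_LIMITS,
    DynamicsConfig,
    JointState,
    ModelParameters,
    MuscleParameters,
    MUSCLES,
    NO_MCP,
    PARAM_BOUNDS,
    PARAM_FIELDS,
    simulate_cycle,
)

__all__ = [
    "SyntheticSubject",
    "make_generic_params",
    "sample_subject",
    "generate_activation_drive",
    "generate_data_cycle",
    "generate_subject_cycles",
    "make_dataset",
    "generate_dataset",
]

#: burst centers (s) for ECRL, FCR (wrist ext/flex) then EDC, FDS (MCP
#: ext/flex) within the 10 s cycle, and the common burst width (s)
BURST_CENTERS = {"ecrl": 1.3, "fcr": 3.3, "edc": 6.0, "fds": 8.0}
BURST_WIDTH = 1.6
AMPLITUDE_RANGE = (0.3, 0.9)


def make_generic_params() -> ModelParameters:
    """Mid-range generic model: every parameter at the midpoint of its
    admissible range, with the structurally zero MCP moment arms of the
    wrist-only muscles."""
    muscles = []
    for name in MUSCLES:
        vals = {f: 0.5 * (PARAM_BOUNDS[f][0] + PARAM_BOUNDS[f][1])
                for f in PARAM_FIELDS}
        if name in NO_MCP:
            vals["ma_mcp"] = 0.0
        muscles.append(MuscleParameters(name=name, **vals))
    return ModelParameters(tuple(muscles)).validate()


@dataclass(frozen=True)
class SyntheticSubject:
    """Ground-truth parameters plus per-channel EMG gain and noise level.

    ``burst_amps`` are the subject's habitual excitation burst amplitudes,
    one per channel: the recording protocol paces subjects with a virtual
    hand, so effort is stereotyped across a subject's cycles and varies
    mainly between subjects.
    """

    params: ModelParameters
    emg_gain: tuple        # per-channel multiplicative gain
    burst_amps: tuple      # per-channel excitation amplitude in [0.3, 0.9]
    noise_sigma_deg: float  # angle measurement noise (deg)
    seed: int

    def __post_init__(self) -> None:
        self.params.validate()
        if self.noise_sigma_deg < 0:
            raise ValueError("noise level must be >= 0")


def sample_subject(seed: int, rho: float = 0.2,
                   noise_sigma_deg: float = 1.0) -> SyntheticSubject:
    """Draw a subject uniformly within ±rho·range of the generic parameters.

    ``rho`` controls how far the subject deviates from the generic model
    (0 = identical); draws are clipped to the parameter bounds and the
    structural zeros are preserved. Per-channel EMG gains are drawn in
    [0.85, 1.15], emulating imperfect MVC normalization.
    """
    if not 0.0 <= rho <= 0.5:
        raise ValueError("perturbation fraction rho must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    generic = make_generic_params().to_vector()
    bl, bu = ModelParameters.bounds_vectors()
    span = rho * (bu - bl)
    vec = np.clip(rng.uniform(generic - span, generic + span), bl, bu)
    gains = tuple(rng.uniform(0.85, 1.15, size=len(CHANNELS)))
    amps = tuple(rng.uniform(*AMPLITUDE_RANGE, size=len(CHANNELS)))
    return SyntheticSubject(params=ModelParameters.from_vector(vec),
                            emg_gain=gains, burst_amps=amps,
                            noise_sigma_deg=noise_sigma_deg, seed=seed)


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Hann-shaped burst supported on [center - width/2, center + width/2]."""
    x = (t - center) / width
    burst = np.where(np.abs(x) <= 0.5, 0.5 * (1.0 + np.cos(2 * np.pi * x)), 0.0)
    return burst


def generate_activation_drive(n_samples: int = 1000, fs: float = 100.0,
                              rng: np.random.Generator | None = None,
                              jitter_s: float = 0.0,
                              amplitudes: np.ndarray | None = None,
                              amp_jitter: float = 0.0) -> np.ndarray:
    """Four-channel excitation template for one cycle, shape (n, 4).

    ECRL then FCR bursts drive wrist extension/flexion in the first half of
    the cycle; EDC then FDS bursts drive MCP extension/flexion in the second
    half. Burst amplitudes lie in [0.3, 0.9] — drawn per channel unless
    ``amplitudes`` fixes them (then only jittered by ±``amp_jitter``) — and
    centers may be jittered by up to ±``jitter_s`` seconds (small enough to
    preserve the burst ordering).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if jitter_s < 0 or jitter_s > 0.5:
        raise ValueError("timing jitter must be in [0, 0.5] s")
    t = np.arange(n_samples) / fs
    drive = np.zeros((n_samples, len(CHANNELS)))
    for i, ch in enumerate(CHANNELS):
        if amplitudes is None:
            amp = rng.uniform(*AMPLITUDE_RANGE)
        else:
            amp = amplitudes[i]
            if amp_jitter > 0:
                amp += rng.uniform(-amp_jitter, amp_jitter)
            amp = min(max(amp, AMPLITUDE_RANGE[0]), AMPLITUDE_RANGE[1])
        center = BURST_CENTERS[ch]
        if jitter_s > 0:
            center = center + rng.uniform(-jitter_s, jitter_s)
        drive[:, i] = amp * _raised_cosine(t, center, BURST_WIDTH)
    return np.clip(drive, 0.0, 1.0)


def generate_data_cycle(subject: SyntheticSubject,
                        constants: ActivationConstants = ActivationConstants(),
                        dynamics: DynamicsConfig = DynamicsConfig(),
                        sigma_deg: float | None = None,
                        rng: np.random.Generator | None = None,
                        jitter_s: float = 0.1,
                        emg_noise: float = 0.02,
                        amp_jitter: float = 0.05) -> DataCycle:
    """One synthetic 10 s data cycle for a subject.

    The emitted EMG is the excitation template scaled by the subject's
    per-channel gain with multiplicative white jitter (clipped at 0). The
    noiseless angles are the model's own simulation of that emitted EMG with
    the subject's true parameters; "measured" angles add Gaussian noise of
    ``sigma_deg`` degrees (subject default), clipped to the joint limits.
    With ``sigma_deg = 0`` the measured series equal the simulation exactly.
    """
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    if sigma_deg is None:
        sigma_deg = subject.noise_sigma_deg
    drive = generate_activation_drive(rng=rng, jitter_s=jitter_s,
                                      amplitudes=np.asarray(subject.burst_amps),
                                      amp_jitter=amp_jitter)
    gain = np.asarray(subject.emg_gain)
    emg = drive * gain
    if emg_noise > 0:
        emg = emg * (1.0 + emg_noise * rng.standard_normal(emg.shape))
    emg = np.clip(emg, 0.0, None)
    est = simulate_cycle(EmgEnvelope(emg), subject.params, constants,
                         init=JointState(), dynamics=dynamics)
    wrist, mcp = est.wrist_deg, est.mcp_deg
    measured_w, measured_m = wrist, mcp
    if sigma_deg > 0:
        measured_w = np.clip(wrist + sigma_deg * rng.standard_normal(wrist.shape),
                             *WRIST_LIMITS)
        measured_m = np.clip(mcp + sigma_deg * rng.standard_normal(mcp.shape),
                             *MCP_LIMITS)
    return DataCycle(emg=emg, wrist_deg=measured_w, mcp_deg=measured_m,
                     noiseless_wrist=wrist, noiseless_mcp=mcp)


def generate_subject_cycles(subject: SyntheticSubject, n_cycles: int,
                            constants: ActivationConstants = ActivationConstants(),
                            dynamics: DynamicsConfig = DynamicsConfig(),
                            sigma_deg: float | None = None) -> list:
    """``n_cycles`` independent cycles from one subject's RNG stream."""
    rng = np.random.default_rng(subject.seed)
    return [generate_data_cycle(subject, constants, dynamics,
                                sigma_deg=sigma_deg, rng=rng)
            for _ in range(n_cycles)]


def make_dataset(n_subjects: int, n_cycles: int, seed: int = 0,
                 rho: float = 0.2, sigma_deg: float = 1.0,
                 constants: ActivationConstants = ActivationConstants(),
                 dynamics: DynamicsConfig = DynamicsConfig()) -> list:
    """In-memory dataset: list of ``(SyntheticSubject, [DataCycle, ...])``."""
    if n_subjects < 1 or n_cycles < 1:
        raise ValueError("need at least one subject and one cycle")
    out = []
    for i in range(n_subjects):
        subj = sample_subject(seed=seed * 10_000 + i, rho=rho,
                              noise_sigma_deg=sigma_deg)
        out.append((subj, generate_subject_cycles(subj, n_cycles, constants,
                                                  dynamics)))
    return out


def generate_dataset(n_subjects: int, n_cycles: int, seed: int, out_dir,
                     rho: float = 0.2, sigma_deg: float = 1.0) -> dict:
    """Write a dataset tree and return its manifest.

    Layout: ``out_dir/subject_XX/cycle_YY.csv`` plus the subject's true
    parameters as ``params.json``; a top-level ``manifest.json`` records the
    generation settings and per-file checksums, so identical seeds produce
    identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = make_dataset(n_subjects, n_cycles, seed=seed, rho=rho,
                           sigma_deg=sigma_deg)
    manifest = {"n_subjects": n_subjects, "n_cycles": n_cycles, "seed": seed,
                "rho": rho, "sigma_deg": sigma_deg, "subjects": {}}
    for i, (subj, cycles) in enumerate(dataset, start=1):
        sdir = out / f"subject_{i:02d}"
        sdir.mkdir(exist_ok=True)
        subj.params.save(sdir / "params.json")
        files = {}
        for j, cyc in enumerate(cycles, start=1):
            path = sdir / f"cycle_{j:02d}.csv"
            save_cycle_csv(cyc, path)
            files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["subjects"][sdir.name] = {
            "seed": subj.seed, "emg_gain": list(subj.emg_gain), "files": files,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
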