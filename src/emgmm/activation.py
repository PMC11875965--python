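"""EMG processing and muscle activation dynamics.

Surface EMG recorded over the four forearm muscles (ECRL, EDC, FCR, FDS) is
converted to a muscle activation signal in three stages:

1. envelope extraction — mean absolute value (MAV) over a 200 ms sliding
   window stepped every 10 ms, turning 1000 Hz raw EMG into a 100 Hz envelope;
2. amplitude normalization by each channel's maximum voluntary contraction
   (MVC) level, yielding the normalized excitation ``e(t)``;
3. activation dynamics — a second-order discrete recursion with an
   electromechanical delay ``d`` producing neural activation ``u(t)``,

       u(t) = alpha * e(t - d) - beta1 * u(t-1) - beta2 * u(t-2)

   followed by a nonlinear shaping to muscle activation ``a(t)``,

       a(t) = (exp(A * u(t)) - 1) / (exp(A) - 1),   A < 0.

The recursion is a standard IIR filter and is evaluated with
:func:`scipy.signal.lfilter`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import lfilter

__all__ = [
    "ActivationConstants",
    "EmgEnvelope",
    "CHANNELS",
    "envelope_emg",
    "normalize_by_mvc",
    "neural_activation",
    "muscle_activation",
    "activation_from_envelope",
]

#: Channel order used throughout the package (one EMG channel per muscle).
CHANNELS = ("ecrl", "edc", "fcr", "fds")


class ConfigurationError(ValueError):
    """Raised for activation constants that violate their invariants."""


@dataclass(frozen=True)
class ActivationConstants:
    """Constants of the two-stage activation dynamics.

    Parameters
    ----------
    alpha, beta1, beta2
        Gains of the second-order recursion. Stability requires the roots of
        ``z**2 + beta1*z + beta2`` to lie strictly inside the unit circle, and
        unity steady-state gain requires ``alpha == 1 + beta1 + beta2`` so a
        sustained excitation ``e`` maps to ``u == e``.
    A
        Shape factor of the nonlinear excitation-to-activation map; negative
        values give the physiologically observed concave relation.
    d_ms
        Electromechanical delay in milliseconds, applied as a whole-sample
        shift on the 100 Hz envelope (40 ms -> 4 samples).
    """

    alpha: float = 0.25
    beta1: float = -1.0
    beta2: float = 0.25
    A: float = -1.0
    d_ms: float = 40.0

    def __post_init__(self) -> None:
        roots = np.roots([1.0, self.beta1, self.beta2])
        if np.any(np.abs(roots) >= 1.0):
            raise ConfigurationError(
                f"unstable recursion: poles {roots} not inside the unit circle"
            )
        if abs(self.alpha - (1.0 + self.beta1 + self.beta2)) > 1e-9:
            raise ConfigurationError(
                "alpha must equal 1 + beta1 + beta2 for unity steady-state gain"
            )
        if self.A > 0:
            raise ConfigurationError("shape factor A must be <= 0")
        if self.d_ms < 0:
            raise ConfigurationError("delay d must be >= 0")

    @property
    def delay_samples(self) -> int:
        """Delay in whole samples at the 100 Hz envelope rate."""
        return int(round(self.d_ms / 10.0))

    @classmethod
    def from_dict(cls, d: dict) -> "ActivationConstants":
        return cls(**{k: d[k] for k in ("alpha", "beta1", "beta2", "A", "d_ms") if k in d})


@dataclass
class EmgEnvelope:
    """A multi-channel 100 Hz EMG envelope.

    ``data`` has shape ``(n_samples, n_channels)`` with channels ordered as
    :data:`CHANNELS`; all samples are non-negative.
    """

    data: np.ndarray
    fs: float = 100.0
    channels: tuple = CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("envelope data must be 2-D (samples, channels)")
        if np.any(self.data < 0):
            raise ValueError("envelope samples must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def envelope_emg(raw: np.ndarray, fs: float = 1000.0, window_ms: float = 200.0,
                 step_ms: float = 10.0) -> EmgEnvelope:
    """Mean-absolute-value envelope of raw EMG.

    A ``window_ms`` window slides over the rectified signal in ``step_ms``
    increments; each output sample is the MAV of one fully contained window,
    so a 1000 Hz input yields a 100 Hz envelope (first output at the first
    complete window).

    Parameters
    ----------
    raw
        Raw EMG, shape ``(n,)`` or ``(n, n_channels)``, sampled at ``fs``.
    """
    raw = np.asarray(raw, dtype=float)
    squeeze = raw.ndim == 1
    if squeeze:
        raw = raw[:, None]
    win = int(round(window_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    if win % step != 0:
        raise ValueError("window_ms must be divisible by step_ms")
    if raw.shape[0] < win:
        raise ValueError(
            f"signal length {raw.shape[0]} shorter than one {win}-sample window"
        )
    windows = sliding_window_view(np.abs(raw), win, axis=0)[::step]
    env = windows.mean(axis=-1)
    return EmgEnvelope(env, fs=1000.0 / step_ms)


def normalize_by_mvc(envelope: EmgEnvelope, mvc_level: np.ndarray) -> EmgEnvelope:
    """Divide each channel by its MVC-level envelope amplitude.

    Values may exceed 1 — dynamic contractions can transiently produce more
    activity than the static MVC trial, so no clipping is applied here.
    """
    mvc = np.atleast_1d(np.asarray(mvc_level, dtype=float))
    if np.any(mvc <= 0):
        raise ValueError("MVC levels must be strictly positive")
    if mvc.size not in (1, envelope.data.shape[1]):
        raise ValueError("one MVC level per channel required")
    return EmgEnvelope(envelope.data / mvc, fs=envelope.fs, channels=envelope.channels)


def neural_activation(e: np.ndarray, constants: ActivationConstants) -> np.ndarray:
    """Second-order recursive activation dynamics with delay.

    Implements ``u(t) = alpha*e(t-d) - beta1*u(t-1) - beta2*u(t-2)`` with zero
    initial conditions (``u(t) = 0`` and ``e(t) = 0`` for ``t < 0``) on a
    100 Hz series; the output is clipped to [0, 1] so the downstream nonlinear
    map's domain holds.
    """
    e = np.asarray(e, dtype=float)
    d = constants.delay_samples
    shifted = np.zeros_like(e)
    if d == 0:
        shifted = e
    elif d < e.shape[0]:
        shifted[d:] = e[:-d] if d else e
    u = lfilter([constants.alpha], [1.0, constants.beta1, constants.beta2],
                shifted, axis=0)
    return np.clip(u, 0.0, 1.0)


def muscle_activation(u: np.ndarray, A: float) -> np.ndarray:
    """Nonlinear neural-to-muscle activation map ``(e^{Au} - 1)/(e^A - 1)``.

    ``A = 0`` is the identity limit and returns ``u`` unchanged.
    """
    u = np.asarray(u, dtype=float)
    if A == 0.0:
        return u.copy()
    return np.expm1(A * u) / np.expm1(A)


def activation_from_envelope(e: np.ndarray, constants: ActivationConstants) -> np.ndarray:
    """Full chain from normalized envelope to muscle activation a(t)."""
    return muscle_activation(neural_activation(e, constants), constants.A)
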