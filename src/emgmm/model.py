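"""Lumped-parameter EMG-driven musculoskeletal model of the wrist and MCP.

Four Hill-type muscles — extensor carpi radialis longus (ECRL), extensor
digitorum communis (EDC), flexor carpi radialis (FCR) and flexor digitorum
superficialis (FDS) — each driven by one EMG channel, produce moments about
the wrist and middle-finger metacarpophalangeal (MCP) joints. The moments
drive a planar two-degree-of-freedom link-segment forward-dynamics model to
estimate joint kinematics.

Each muscle has six parameters: optimal contractile-element (CE) length
``l_opt`` (m), maximum isometric force ``F0_CE`` (N), wrist and MCP moment
arms (m), CE length in the neutral posture ``l_theta0`` (% of ``l_opt``) and
passive-element stiffness ``K_PEE`` (N/m^2). ECRL and FCR do not cross the
MCP joint, so their MCP moment arms are structurally zero, leaving 22
optimizable parameters in total.

Conventions: flexion positive for both joints; flexor muscles carry moment
sign +1 and extensors -1; a muscle shortens under the motion it drives, so
its CE length is ``(l_theta0/100)*l_opt - sgn*(ma_w*theta_w + ma_m*theta_m)``
with angles in radians.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._dynamics import simulate_kernel
from .activation import ActivationConstants, EmgEnvelope, activation_from_envelope

__all__ = [
    "MUSCLES",
    "PARAM_FIELDS",
    "PARAM_BOUNDS",
    "WRIST_LIMITS",
    "MCP_LIMITS",
    "WRIST_ROM",
    "MCP_ROM",
    "MuscleParameters",
    "ModelParameters",
    "JointState",
    "KinematicsEstimate",
    "DynamicsConfig",
    "ModelDegeneracyError",
    "ce_length",
    "muscle_force",
    "joint_moments",
    "forward_dynamics_step",
    "simulate_cycle",
    "vector_to_matrix",
    "simulate_activation_matrix",
]

MUSCLES = ("ECRL", "EDC", "FCR", "FDS")
PARAM_FIELDS = ("l_opt", "F0_CE", "ma_wrist", "ma_mcp", "l_theta0", "K_PEE")

#: (lower, upper) bound per parameter field
PARAM_BOUNDS = {
    "l_opt": (0.1, 0.5),
    "F0_CE": (10.0, 1000.0),
    "ma_wrist": (0.001, 0.05),
    "ma_mcp": (0.001, 0.05),
    "l_theta0": (75.0, 125.0),
    "K_PEE": (10.0, 200.0),
}

ROLES = {
    "ECRL": "wrist-extensor",
    "EDC": "mcp-extensor",
    "FCR": "wrist-flexor",
    "FDS": "mcp-flexor",
}
#: muscles whose MCP moment arm is structurally zero
NO_MCP = ("ECRL", "FCR")

WRIST_LIMITS = (-75.0, 75.0)
MCP_LIMITS = (-10.0, 90.0)
WRIST_ROM = WRIST_LIMITS[1] - WRIST_LIMITS[0]
MCP_ROM = MCP_LIMITS[1] - MCP_LIMITS[0]


class ModelDegeneracyError(ValueError):
    """A parameter/posture combination produced a non-positive CE length."""


@dataclass(frozen=True)
class MuscleParameters:
    """The six Hill-model parameters of one muscle (see module docstring)."""

    name: str
    l_opt: float
    F0_CE: float
    ma_wrist: float
    ma_mcp: float
    l_theta0: float
    K_PEE: float

    @property
    def role(self) -> str:
        return ROLES[self.name]

    @property
    def sign(self) -> int:
        """+1 for flexors, -1 for extensors (flexion-positive convention)."""
        return 1 if "flexor" in self.role else -1

    def validate(self) -> None:
        for f in PARAM_FIELDS:
            lo, hi = PARAM_BOUNDS[f]
            v = getattr(self, f)
            if f == "ma_mcp" and self.name in NO_MCP:
                if v != 0.0:
                    raise ValueError(f"{self.name}.ma_mcp must be 0")
                continue
            if not lo <= v <= hi:
                raise ValueError(f"{self.name}.{f}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ModelParameters:
    """All four muscles; 22 optimizable values.

    The flat-vector interchange order is [ECRL, EDC, FCR, FDS] x
    [l_opt, F0_CE, ma_wrist, ma_mcp, l_theta0, K_PEE] with the two structural
    zeros (ma_mcp of ECRL and FCR) omitted, giving a length-22 vector aligned
    with the bounds vectors ``BL`` and ``BU``.
    """

    muscles: tuple  # four MuscleParameters in MUSCLES order

    def __post_init__(self) -> None:
        if tuple(m.name for m in self.muscles) != MUSCLES:
            raise ValueError(f"muscles must be in order {MUSCLES}")

    def validate(self) -> "ModelParameters":
        for m in self.muscles:
            m.validate()
        return self

    def __getitem__(self, name: str) -> MuscleParameters:
        return self.muscles[MUSCLES.index(name)]

    # -- flat-vector interchange ------------------------------------------

    @staticmethod
    def vector_index() -> list:
        """(muscle, field) pairs in flat-vector order (length 22)."""
        return [
            (m, f)
            for m in MUSCLES
            for f in PARAM_FIELDS
            if not (f == "ma_mcp" and m in NO_MCP)
        ]

    @staticmethod
    def bounds_vectors() -> tuple:
        """Lower/upper bounds (BL, BU) aligned with the flat vector."""
        idx = ModelParameters.vector_index()
        bl = np.array([PARAM_BOUNDS[f][0] for _, f in idx])
        bu = np.array([PARAM_BOUNDS[f][1] for _, f in idx])
        return bl, bu

    def to_vector(self) -> np.ndarray:
        return np.array(
            [getattr(self[m], f) for m, f in self.vector_index()], dtype=float
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (22,):
            raise ValueError(f"expected a 22-vector, got shape {vec.shape}")
        values = {m: {"ma_mcp": 0.0} for m in MUSCLES}
        for (m, f), v in zip(cls.vector_index(), vec):
            values[m][f] = float(v)
        return cls(tuple(MuscleParameters(name=m, **values[m]) for m in MUSCLES))

    def to_matrix(self) -> np.ndarray:
        """(4, 6) array in MUSCLES x PARAM_FIELDS order (kernel layout)."""
        return np.array(
            [[getattr(m, f) for f in PARAM_FIELDS] for m in self.muscles]
        )

    @property
    def signs(self) -> np.ndarray:
        return np.array([m.sign for m in self.muscles], dtype=float)

    # -- JSON serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            m.name: {f: getattr(m, f) for f in PARAM_FIELDS} for m in self.muscles
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            tuple(MuscleParameters(name=m, **d[m]) for m in MUSCLES)
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class JointState:
    """Wrist and MCP angles (deg, flexion positive) and velocities (deg/s)."""

    theta_wrist: float = 0.0
    theta_mcp: float = 45.0
    omega_wrist: float = 0.0
    omega_mcp: float = 0.0

    def clamped(self) -> "JointState":
        s = replace(self)
        if s.theta_wrist <= WRIST_LIMITS[0]:
            s.theta_wrist, s.omega_wrist = WRIST_LIMITS[0], 0.0
        elif s.theta_wrist >= WRIST_LIMITS[1]:
            s.theta_wrist, s.omega_wrist = WRIST_LIMITS[1], 0.0
        if s.theta_mcp <= MCP_LIMITS[0]:
            s.theta_mcp, s.omega_mcp = MCP_LIMITS[0], 0.0
        elif s.theta_mcp >= MCP_LIMITS[1]:
            s.theta_mcp, s.omega_mcp = MCP_LIMITS[1], 0.0
        return s


@dataclass
class KinematicsEstimate:
    """Estimated wrist and MCP angle series (deg) at 100 Hz."""

    wrist_deg: np.ndarray
    mcp_deg: np.ndarray
    fs: float = 100.0

    @property
    def n_samples(self) -> int:
        return self.wrist_deg.shape[0]


@dataclass(frozen=True)
class DynamicsConfig:
    """Link-segment dynamics constants.

    Inertias are of the hand about the wrist and of the finger about the MCP;
    viscous damping dominates the response (b/I time constants of a few
    milliseconds), giving smooth, physiological joint velocities of order
    100-400 deg/s with mid-range muscle parameters.
    """

    I_wrist: float = 5e-3   # kg m^2
    I_mcp: float = 1e-3     # kg m^2
    b_wrist: float = 3.0    # N m s / rad
    b_mcp: float = 1.5      # N m s / rad
    dt: float = 0.01        # s
    fl_width: float = 0.45  # Gaussian force-length width (dimensionless)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.I_wrist, self.I_mcp, self.b_wrist, self.b_mcp, self.dt,
             self.fl_width]
        )

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicsConfig":
        return cls(**d)


# flat positions of the 22 optimizable values inside the (4, 6) kernel matrix
_VEC_FLAT_POS = np.array(
    [MUSCLES.index(m) * len(PARAM_FIELDS) + PARAM_FIELDS.index(f)
     for m, f in ModelParameters.vector_index()]
)
_MUSCLE_SIGNS = np.array([-1.0, -1.0, 1.0, 1.0])  # ECRL, EDC, FCR, FDS
_LIMITS = np.array([*WRIST_LIMITS, *MCP_LIMITS])


def vector_to_matrix(vec: np.ndarray) -> np.ndarray:
    """Flat 22-vector -> (4, 6) kernel parameter matrix (structural zeros
    restored). Fast path for optimizer inner loops."""
    mat = np.zeros(len(MUSCLES) * len(PARAM_FIELDS))
    mat[_VEC_FLAT_POS] = vec
    return mat.reshape(len(MUSCLES), len(PARAM_FIELDS))


def simulate_activation_matrix(act: np.ndarray, mat: np.ndarray,
                               dynamics: "DynamicsConfig",
                               init: np.ndarray | None = None,
                               clamp: bool = False) -> tuple:
    """Run the jitted kernel on precomputed activations.

    Returns ``(wrist_deg, mcp_deg, min_lce)``; callers decide how to treat a
    non-positive minimum CE length.
    """
    if init is None:
        init = np.array([0.0, 45.0, 0.0, 0.0])
    return simulate_kernel(act, mat, _MUSCLE_SIGNS, _LIMITS,
                           dynamics.to_array(), init, clamp)


# ---------------------------------------------------------------------------
# elementary operations (reference implementations; the jitted kernel in
# _dynamics.py fuses them for whole-cycle simulation)
# ---------------------------------------------------------------------------

def ce_length(muscle: MuscleParameters, state: JointState) -> float:
    """Contractile-element length (m) at the given posture."""
    th_w = math.radians(state.theta_wrist)
    th_m = math.radians(state.theta_mcp)
    lce = (muscle.l_theta0 / 100.0) * muscle.l_opt - muscle.sign * (
        muscle.ma_wrist * th_w + muscle.ma_mcp * th_m
    )
    if lce <= 0:
        raise ModelDegeneracyError(
            f"{muscle.name}: non-positive CE length {lce:.4f} m at "
            f"wrist={state.theta_wrist:.1f} deg, mcp={state.theta_mcp:.1f} deg"
        )
    return lce


def muscle_force(a: float, muscle: MuscleParameters, state: JointState,
                 dynamics: DynamicsConfig = DynamicsConfig()) -> float:
    """Total muscle force (N): Gaussian active force-length curve plus a
    quadratic passive elastic element engaged beyond the optimal length."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must be in [0, 1]")
    lce = ce_length(muscle, state)
    lt = lce / muscle.l_opt
    f = muscle.F0_CE * a * math.exp(-((lt - 1.0) ** 2) / dynamics.fl_width)
    if lce > muscle.l_opt:
        f += muscle.K_PEE * (lce - muscle.l_opt) ** 2
    return f


def joint_moments(forces: np.ndarray, params: ModelParameters) -> tuple:
    """Net (wrist, MCP) moments in N m from the four muscle forces."""
    forces = np.asarray(forces, dtype=float)
    m_w = m_m = 0.0
    for f, m in zip(forces, params.muscles):
        m_w += m.sign * m.ma_wrist * f
        m_m += m.sign * m.ma_mcp * f
    return m_w, m_m


def forward_dynamics_step(state: JointState, moments: tuple,
                          dynamics: DynamicsConfig = DynamicsConfig()) -> JointState:
    """One integration step of ``I*theta'' = M - b*theta'``.

    Velocity is updated first (damping treated implicitly, which keeps the
    step stable for strongly damped joints), then position; angles are clamped
    at the joint limits with velocity zeroed.
    """
    dt = dynamics.dt
    out = JointState(state.theta_wrist, state.theta_mcp, 0.0, 0.0)
    for joint, (M, I, b) in {
        "wrist": (moments[0], dynamics.I_wrist, dynamics.b_wrist),
        "mcp": (moments[1], dynamics.I_mcp, dynamics.b_mcp),
    }.items():
        om = math.radians(getattr(state, f"omega_{joint}"))
        th = math.radians(getattr(state, f"theta_{joint}"))
        om = (om + dt * M / I) / (1.0 + dt * b / I)
        th += dt * om
        setattr(out, f"theta_{joint}", math.degrees(th))
        setattr(out, f"omega_{joint}", math.degrees(om))
    return out.clamped()


def simulate_cycle(emg: EmgEnvelope, params: ModelParameters,
                   constants: ActivationConstants = ActivationConstants(),
                   init: JointState = None,
                   dynamics: DynamicsConfig = DynamicsConfig(),
                   on_degenerate: str = "raise") -> KinematicsEstimate:
    """Estimate joint kinematics for one EMG cycle.

    Chains activation dynamics -> muscle forces -> joint moments -> forward
    dynamics at the 100 Hz envelope rate. Fully deterministic.

    ``on_degenerate`` controls what happens if a proposed parameter set drives
    the CE length non-positive: ``"raise"`` (default) raises
    :class:`ModelDegeneracyError`; ``"clamp"`` floors the length at 1 mm,
    which optimizers use so that infeasible excursions remain evaluable.
    """
    if init is None:
        init = JointState()
    act = activation_from_envelope(emg.data, constants)
    limits = np.array([*WRIST_LIMITS, *MCP_LIMITS])
    init_arr = np.array(
        [init.theta_wrist, init.theta_mcp, init.omega_wrist, init.omega_mcp]
    )
    wrist, mcp, min_lce = simulate_kernel(
        act, params.to_matrix(), params.signs, limits, dynamics.to_array(),
        init_arr, on_degenerate == "clamp"
    )
    if on_degenerate == "raise" and min_lce <= 0:
        raise ModelDegeneracyError(
            f"non-positive CE length ({min_lce:.4f} m) during simulation"
        )
    return KinematicsEstimate(wrist_deg=wrist, mcp_deg=mcp)
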