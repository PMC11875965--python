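"""Simulated-annealing baseline for model calibration.

The 22 parameters are affinely normalized to the unit box; the objective is
the sum of squared ROM-normalized joint-angle estimation errors over all
provided training cycles. The annealer uses the conventional defaults of
bounded SA solvers: initial temperature 100, exponential cooling
``T = T0 * 0.95**floor(k/20)``, Gaussian proposal steps scaled by the
temperature (capped at the box size) and the logistic acceptance rule
``1 / (1 + exp(dF/T))`` for uphill moves. Equivalence with any particular
solver is behavioral (objective reduction), not bit-level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import ActivationConstants
from .model import (
    MCP_ROM,
    WRIST_ROM,
    DynamicsConfig,
    JointState,
    ModelDegeneracyError,
    ModelParameters,
    simulate_activation_matrix,
    simulate_cycle,
    vector_to_matrix,
)
from .rl import cycle_activation

__all__ = [
    "SaConfig",
    "SaResult",
    "sa_objective",
    "normalize_params",
    "denormalize_params",
    "simulated_annealing",
    "sa_optimize",
]


@dataclass(frozen=True)
class SaConfig:
    """Annealing schedule. ``max_iters`` is the evaluation budget."""

    t0: float = 100.0
    cooling: float = 0.95
    cooling_interval: int = 20
    max_iters: int = 5000
    reanneal_interval: int = 10_000  # acceptances; default effectively off

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("initial temperature must be > 0")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.max_iters < 0:
            raise ValueError("iteration cap must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SaConfig":
        return cls(**d)


@dataclass
class SaResult:
    params: ModelParameters
    objective: float
    trace: pd.DataFrame  # iter, temperature, objective, best_objective
    evaluations: int


def sa_objective(params: ModelParameters, cycles: list,
                 constants: ActivationConstants = ActivationConstants(),
                 dynamics: DynamicsConfig = DynamicsConfig()) -> float:
    """Sum of squared ROM-normalized errors over all cycles and both joints.

    Degenerate parameter sets (non-positive muscle length somewhere in the
    cycle) are infeasible and score +inf.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    total = 0.0
    for cyc in cycles:
        try:
            est = simulate_cycle(cyc.envelope, params, constants,
                                 init=JointState(), dynamics=dynamics)
        except ModelDegeneracyError:
            return math.inf
        total += float(np.sum(((cyc.wrist_deg - est.wrist_deg) / WRIST_ROM) ** 2))
        total += float(np.sum(((cyc.mcp_deg - est.mcp_deg) / MCP_ROM) ** 2))
    return total


def normalize_params(p: np.ndarray, bl: np.ndarray, bu: np.ndarray) -> np.ndarray:
    """Map a bounded 22-vector to the unit box."""
    p = np.asarray(p, dtype=float)
    if np.any(p < bl - 1e-12) or np.any(p > bu + 1e-12):
        raise ValueError("parameters outside their bounds")
    return (p - bl) / (bu - bl)


def denormalize_params(x: np.ndarray, bl: np.ndarray, bu: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("normalized parameters must lie in [0, 1]")
    return bl + x * (bu - bl)


def simulated_annealing(objective, x0: np.ndarray, config: SaConfig = SaConfig(),
                        seed: int = 0) -> tuple:
    """Minimize ``objective`` over the unit box from ``x0``.

    Returns ``(best_x, best_f, trace)`` with a per-iteration trace frame.
    Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    f = float(objective(x))
    best_x, best_f = x.copy(), f
    rows = []
    accepted = 0
    k_offset = 0
    for k in range(config.max_iters):
        t = config.t0 * config.cooling ** ((k - k_offset) // config.cooling_interval)
        step = min(t, 1.0)
        cand = np.clip(x + step * rng.standard_normal(x.shape), 0.0, 1.0)
        f_cand = float(objective(cand))
        delta = f_cand - f
        if delta <= 0 or rng.random() < 1.0 / (1.0 + math.exp(min(delta / t, 700.0))):
            x, f = cand, f_cand
            accepted += 1
            if f < best_f:
                best_x, best_f = x.copy(), f
            if accepted % config.reanneal_interval == 0:
                k_offset = k  # reset the cooling clock, keep the incumbent
        rows.append((k, t, f_cand, best_f))
    trace = pd.DataFrame(rows, columns=["iter", "temperature", "objective",
                                        "best_objective"])
    return best_x, best_f, trace


def sa_optimize(cycles: list, generic: ModelParameters,
                config: SaConfig = SaConfig(), seed: int = 0,
                constants: ActivationConstants = ActivationConstants(),
                dynamics: DynamicsConfig = DynamicsConfig()) -> SaResult:
    """Calibrate the model to the given cycles by simulated annealing."""
    bl, bu = ModelParameters.bounds_vectors()
    x0 = normalize_params(generic.to_vector(), bl, bu)
    prepared = [(cycle_activation(c, constants), c.wrist_deg, c.mcp_deg)
                for c in cycles]

    def obj(x: np.ndarray) -> float:
        mat = vector_to_matrix(denormalize_params(x, bl, bu))
        total = 0.0
        for act, mw, mm in prepared:
            wrist, mcp, min_lce = simulate_activation_matrix(act, mat, dynamics)
            if min_lce <= 0:
                return math.inf
            total += float(np.sum(((mw - wrist) / WRIST_ROM) ** 2))
            total += float(np.sum(((mm - mcp) / MCP_ROM) ** 2))
        return total

    best_x, best_f, trace = simulated_annealing(obj, x0, config, seed)
    return SaResult(
        params=ModelParameters.from_vector(denormalize_params(best_x, bl, bu)),
        objective=best_f, trace=trace,
        evaluations=config.max_iters + 1,
    )
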