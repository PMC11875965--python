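"""Policy-based personalization of the musculoskeletal model.

The personalization problem is cast as a continuous-control task: the *state*
summarizes how the model's estimated joint kinematics deviate from a user's
measured kinematics over one data cycle, the *action* nudges the 22 model
parameters, and the *reward* penalizes the remaining error. A deterministic
policy (actor network) is pretrained across a pool of subjects with the deep
deterministic policy gradient (DDPG) algorithm; personalizing the model for a
new user then amounts to rolling the frozen policy forward for a handful of
update steps until the reward stops improving.

State featurization
-------------------
Eight keypoint timesteps are located in each cycle: the maxima and minima of
the measured wrist and MCP angle series plus the midpoints between them (the
gap between the last and first extremum is closed circularly). Around each
keypoint, the signed estimation error — measured minus estimated angle, both
normalized by the joint's range of motion — is averaged over a 500 ms window
(L = 50 samples at 100 Hz). The eight wrist errors followed by the eight MCP
errors form the 16-element state S, and the reward is the negative L1 norm
r = -||S||_1.

Actions
-------
The actor's tanh output A in [-1, 1]^22 is scaled to parameter updates
dP = k * (BU - BL) * A with k = 0.05, so one step can move each parameter by
at most 5% of its admissible range; updated parameters are clipped to their
bounds.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .activation import ActivationConstants, activation_from_envelope
from .data import DataCycle
from .model import (
    MCP_LIMITS,
    MCP_ROM,
    WRIST_LIMITS,
    WRIST_ROM,
    DynamicsConfig,
    ModelParameters,
    simulate_activation_matrix,
    vector_to_matrix,
)
from .networks import (
    ACTION_DIM,
    ActorNetwork,
    CriticNetwork,
    make_optimizer,
    soft_update,
)

__all__ = [
    "DdpgHyperparams",
    "OuNoise",
    "ReplayBuffer",
    "Transition",
    "find_keypoint_timesteps",
    "compute_state",
    "compute_reward",
    "scale_action",
    "apply_update",
    "cycle_state",
    "cycle_activation",
    "reward_converged",
    "ddpg_pretrain",
    "personalize",
    "PersonalizationResult",
    "PretrainResult",
]

#: samples in the 500 ms error-averaging window at 100 Hz
ERROR_WINDOW = 50


# ---------------------------------------------------------------------------
# state, reward, action
# ---------------------------------------------------------------------------

def find_keypoint_timesteps(wrist: np.ndarray, mcp: np.ndarray) -> np.ndarray:
    """Eight keypoint timesteps of one measured cycle.

    The four extrema (wrist max/min, MCP max/min; earliest index on ties) are
    sorted chronologically; the midpoints of the three gaps between
    consecutive extrema plus the circular midpoint from the last extremum
    back to the first (offset by the cycle length, modulo the cycle) complete
    the eight. Midpoints are floored to whole samples.
    """
    wrist = np.asarray(wrist, dtype=float)
    mcp = np.asarray(mcp, dtype=float)
    if wrist.shape != mcp.shape or wrist.ndim != 1 or wrist.size < 2:
        raise ValueError("need two equal-length 1-D series of length >= 2")
    n = wrist.size
    extrema = sorted(
        int(i)
        for i in (np.argmax(wrist), np.argmin(wrist), np.argmax(mcp), np.argmin(mcp))
    )
    mids = [(extrema[i] + extrema[i + 1]) // 2 for i in range(3)]
    mids.append(((extrema[3] + extrema[0] + n) // 2) % n)
    return np.array(sorted(extrema + mids), dtype=int)


def _normalize_angles(wrist: np.ndarray, mcp: np.ndarray) -> tuple:
    w = (np.asarray(wrist, dtype=float) - WRIST_LIMITS[0]) / WRIST_ROM
    m = (np.asarray(mcp, dtype=float) - MCP_LIMITS[0]) / MCP_ROM
    return w, m


def compute_state(measured_wrist, measured_mcp, est_wrist, est_mcp,
                  timesteps: np.ndarray, L: int = ERROR_WINDOW) -> np.ndarray:
    """16-element state: windowed signed normalized errors at the keypoints.

    Windows of ``L`` samples are centered on each keypoint ([T - L/2, T + L/2))
    and clipped at the cycle boundaries, reducing the averaging length there.
    """
    mw, mm = _normalize_angles(measured_wrist, measured_mcp)
    ew, em = _normalize_angles(est_wrist, est_mcp)
    if mw.shape != ew.shape or mm.shape != em.shape:
        raise ValueError("measured and estimated series must have equal lengths")
    n = mw.size
    # windowed means via cumulative sums (hot path during training)
    cw = np.concatenate(([0.0], np.cumsum(mw - ew)))
    cm = np.concatenate(([0.0], np.cumsum(mm - em)))
    state = np.empty(2 * len(timesteps))
    for i, t in enumerate(timesteps):
        lo = max(0, int(t) - L // 2)
        hi = min(n, int(t) + L // 2)
        state[i] = (cw[hi] - cw[lo]) / (hi - lo)
        state[i + len(timesteps)] = (cm[hi] - cm[lo]) / (hi - lo)
    return state


def compute_reward(state: np.ndarray) -> float:
    """Reward r = -||S||_1 (zero only for a perfect fit)."""
    return float(-np.abs(np.asarray(state, dtype=float)).sum())


def scale_action(action: np.ndarray, bl: np.ndarray, bu: np.ndarray,
                 k: float = 0.05) -> np.ndarray:
    """Parameter updates dP = k * (BU - BL) * A (elementwise)."""
    action = np.asarray(action, dtype=float)
    return k * (bu - bl) * action


def apply_update(p: np.ndarray, dp: np.ndarray, bl: np.ndarray,
                 bu: np.ndarray) -> np.ndarray:
    """P' = clip(P + dP, BL, BU) on the 22-element flat vector.

    The two structurally zero MCP moment arms are not part of the flat
    vector, so they can never be touched by an update.
    """
    return np.clip(np.asarray(p, dtype=float) + dp, bl, bu)


def cycle_activation(cycle: DataCycle,
                     constants: ActivationConstants) -> np.ndarray:
    """Muscle activations for a cycle's EMG, cached on the cycle (they do
    not depend on the model parameters)."""
    act = cycle._act_cache.get(constants)
    if act is None:
        act = activation_from_envelope(cycle.emg, constants)
        cycle._act_cache[constants] = act
    return act


def cycle_state(cycle: DataCycle, params, constants: ActivationConstants,
                dynamics: DynamicsConfig) -> np.ndarray:
    """Simulate one cycle under ``params`` and featurize the errors.

    ``params`` may be a :class:`ModelParameters` or the flat 22-vector.
    Keypoints depend only on the measured series and are cached on the cycle.
    CE-length degeneracies are clamped (optimizer context) rather than raised.
    """
    if cycle._keypoints is None:
        cycle._keypoints = find_keypoint_timesteps(cycle.wrist_deg, cycle.mcp_deg)
    vec = params.to_vector() if isinstance(params, ModelParameters) else params
    wrist, mcp, _ = simulate_activation_matrix(
        cycle_activation(cycle, constants), vector_to_matrix(vec), dynamics,
        clamp=True)
    return compute_state(cycle.wrist_deg, cycle.mcp_deg, wrist, mcp,
                         cycle._keypoints)


# ---------------------------------------------------------------------------
# DDPG machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transition:
    """(S_m, A_m, r_m, S_{m+1})."""

    state: np.ndarray
    action: np.ndarray
    reward: float
    next_state: np.ndarray


class ReplayBuffer:
    """FIFO experience buffer with uniform minibatch sampling.

    Transitions are mirrored into preallocated column arrays (a ring buffer)
    so minibatches can be gathered by fancy indexing in the training loop.
    """

    def __init__(self, capacity: int = 4000, state_dim: int = 16,
                 action_dim: int = ACTION_DIM):
        self._buf: deque = deque(maxlen=capacity)
        self.capacity = capacity
        self._S = np.empty((capacity, state_dim))
        self._A = np.empty((capacity, action_dim))
        self._r = np.empty(capacity)
        self._S1 = np.empty((capacity, state_dim))
        self._head = 0

    def __len__(self) -> int:
        return len(self._buf)

    def add(self, transition: Transition) -> None:
        self._buf.append(transition)
        i = self._head
        self._S[i] = transition.state
        self._A[i] = transition.action
        self._r[i] = transition.reward
        self._S1[i] = transition.next_state
        self._head = (i + 1) % self.capacity

    def __contains__(self, transition: Transition) -> bool:
        return any(t is transition for t in self._buf)

    def sample(self, rng: np.random.Generator, n: int) -> list:
        """Uniform sample of ``n`` distinct transitions."""
        if n > len(self._buf):
            raise ValueError("not enough transitions to sample")
        idx = rng.choice(len(self._buf), size=n, replace=False)
        return [self._buf[i] for i in idx]

    def sample_arrays(self, rng: np.random.Generator, n: int) -> tuple:
        """Uniform sample as stacked arrays (S, A, r, S1)."""
        if n > len(self._buf):
            raise ValueError("not enough transitions to sample")
        idx = rng.choice(len(self._buf), size=n, replace=False)
        return self._S[idx], self._A[idx], self._r[idx], self._S1[idx]


class OuNoise:
    """Ornstein-Uhlenbeck exploration noise.

    Discretized as ``x <- x + theta*(0 - x) + sigma*N(0, 1)`` per step, with
    the standard deviation decaying multiplicatively by the decay rate each
    step (never below zero).
    """

    def __init__(self, dim: int = ACTION_DIM, theta: float = 0.15,
                 sigma: float = 0.30, decay: float = 1e-4):
        self.theta = theta
        self.sigma = sigma
        self.decay = decay
        self.x = np.zeros(dim)

    def reset(self) -> None:
        self.x[:] = 0.0

    def step(self, rng: np.random.Generator) -> np.ndarray:
        self.x += self.theta * (0.0 - self.x)
        if self.sigma > 0:
            self.x += self.sigma * rng.standard_normal(self.x.shape)
        self.sigma = max(self.sigma * (1.0 - self.decay), 0.0)
        return self.x.copy()


@dataclass(frozen=True)
class DdpgHyperparams:
    """Hyperparameters of the DDPG training loop.

    Defaults follow the configuration used for the full-scale training runs,
    except ``episodes`` which defaults to a desk-scale 100 (1000 for the
    full-scale schedule).
    """

    learning_rate: float = 1e-3
    gamma: float = 0.99
    tau: float = 1e-3
    l2: float = 0.0
    buffer_size: int = 4000
    minibatch: int = 100
    ou_std: float = 0.30
    ou_decay: float = 1e-4
    ou_theta: float = 0.15
    episodes: int = 100
    steps_per_episode: int = 20
    k: float = 0.05
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        if self.k <= 0:
            raise ValueError("k must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "DdpgHyperparams":
        return cls(**d)


@dataclass
class PretrainResult:
    actor: ActorNetwork
    critic: CriticNetwork
    episode_rewards: np.ndarray
    simulations: int
    buffer: ReplayBuffer


def _update_networks(rng, buffer, actor, critic, actor_t, critic_t,
                     actor_opt, critic_opt, hp) -> None:
    S, A, r, S1 = buffer.sample_arrays(rng, hp.minibatch)
    y = r + hp.gamma * critic_t(S1, actor_t(S1))
    _, grads = critic.td_gradients(S, A, y)
    critic_opt.apply(critic.weights, grads)
    dA = critic.action_gradient(S, actor(S))
    actor_opt.apply(actor.weights, actor.policy_gradients(S, dA))
    soft_update(critic_t, critic, hp.tau)
    soft_update(actor_t, actor, hp.tau)


def ddpg_pretrain(subjects: list, hyperparams: DdpgHyperparams = DdpgHyperparams(),
                  seed: int = 0, generic: ModelParameters | None = None,
                  constants: ActivationConstants = ActivationConstants(),
                  dynamics: DynamicsConfig = DynamicsConfig(),
                  actor: ActorNetwork | None = None,
                  critic: CriticNetwork | None = None) -> PretrainResult:
    """Pretrain an actor across subjects' data cycles.

    Parameters
    ----------
    subjects
        One list of :class:`DataCycle` per training subject.
    generic
        Initial parameter set used at the start of every episode (defaults to
        the mid-range generic model).
    actor, critic
        Optional pre-initialized networks (warm starts); by default both are
        randomly initialized from the seeded generator.

    Episodes cycle through the subjects; within an episode the update steps
    cycle through the selected subject's data cycles, one cycle per step. The
    state observed after applying an update is computed on the *next* cycle,
    so consecutive steps share one simulation.
    """
    if not subjects or any(len(s) == 0 for s in subjects):
        raise ValueError("need at least one subject with at least one data cycle")
    from .synthetic import make_generic_params  # local import: avoid cycle

    if generic is None:
        generic = make_generic_params()
    rng = np.random.default_rng(seed)
    if actor is None:
        actor = ActorNetwork.init(rng)
    if critic is None:
        critic = CriticNetwork.init(rng)
    actor_t = actor.copy()
    critic_t = critic.copy()
    buffer = ReplayBuffer(hyperparams.buffer_size)
    actor_opt = make_optimizer(hyperparams.optimizer, hyperparams.learning_rate,
                               hyperparams.l2)
    critic_opt = make_optimizer(hyperparams.optimizer, hyperparams.learning_rate,
                                hyperparams.l2)
    noise = OuNoise(theta=hyperparams.ou_theta, sigma=hyperparams.ou_std,
                    decay=hyperparams.ou_decay)
    bl, bu = ModelParameters.bounds_vectors()
    generic_vec = generic.to_vector()
    episode_rewards = np.empty(hyperparams.episodes)
    n_sims = 0

    for ep in range(hyperparams.episodes):
        cycles = subjects[ep % len(subjects)]
        p = generic_vec.copy()
        noise.reset()
        s = cycle_state(cycles[0], p, constants, dynamics)
        n_sims += 1
        rewards = []
        for m in range(hyperparams.steps_per_episode):
            r = compute_reward(s)
            rewards.append(r)
            a = np.clip(actor(s) + noise.step(rng), -1.0, 1.0)
            p = apply_update(p, scale_action(a, bl, bu, hyperparams.k), bl, bu)
            nxt = cycles[(m + 1) % len(cycles)]
            s1 = cycle_state(nxt, p, constants, dynamics)
            n_sims += 1
            buffer.add(Transition(s, a, r, s1))
            if len(buffer) >= hyperparams.minibatch:
                _update_networks(rng, buffer, actor, critic, actor_t, critic_t,
                                 actor_opt, critic_opt, hyperparams)
            s = s1
        episode_rewards[ep] = float(np.mean(rewards))

    return PretrainResult(actor=actor, critic=critic,
                          episode_rewards=episode_rewards, simulations=n_sims,
                          buffer=buffer)


# ---------------------------------------------------------------------------
# personalization with a frozen policy
# ---------------------------------------------------------------------------

def reward_converged(rewards) -> bool:
    """Convergence test on a reward history r_1..r_m.

    The reward change ``dr_i = r_i - r_{i-1}`` is averaged over the last
    three steps; convergence is declared when that average is nonpositive.
    Defined only from m = 4 (three reward changes available); earlier
    histories return False.
    """
    if len(rewards) < 4:
        return False
    dr = np.diff(np.asarray(rewards[-4:], dtype=float))
    return bool(dr.mean() <= 0)


@dataclass
class PersonalizationResult:
    params: ModelParameters
    rewards: np.ndarray
    steps: int
    converged: bool
    evaluations: int  #: number of model simulations performed


def personalize(policy: ActorNetwork, cycles: list,
                generic: ModelParameters | None = None,
                constants: ActivationConstants = ActivationConstants(),
                dynamics: DynamicsConfig = DynamicsConfig(),
                k: float = 0.05, max_steps: int = 200) -> PersonalizationResult:
    """Personalize the model for a new subject with a frozen policy.

    Starting from the generic parameters, each update step loads the next
    data cycle (cyclically), simulates, featurizes the errors and applies the
    noiseless policy action. The reward change ``dr_m = r_m - r_{m-1}`` is
    averaged over a sliding window of 3; the procedure stops at the first
    step (m >= 4) where that average is nonpositive, returning the parameter
    set evaluated at the stopping step. If the ``max_steps`` guard is hit
    first, the best-seen parameters are returned with ``converged=False``.

    Deterministic given (policy, cycles, generic).
    """
    if not cycles:
        raise ValueError("need at least one data cycle")
    from .synthetic import make_generic_params  # local import: avoid cycle

    if generic is None:
        generic = make_generic_params()
    bl, bu = ModelParameters.bounds_vectors()
    p = generic.to_vector()
    rewards: list = []
    best_p, best_r = p.copy(), -np.inf
    for m in range(1, max_steps + 1):
        cyc = cycles[(m - 1) % len(cycles)]
        s = cycle_state(cyc, p, constants, dynamics)
        r = compute_reward(s)
        rewards.append(r)
        if r > best_r:
            best_p, best_r = p.copy(), r
        if reward_converged(rewards):
            return PersonalizationResult(
                params=ModelParameters.from_vector(p),
                rewards=np.array(rewards), steps=m, converged=True,
                evaluations=m)
        a = policy(s)
        p = apply_update(p, scale_action(a, bl, bu, k), bl, bu)
    import warnings

    warnings.warn("personalization hit the step cap without converging; "
                  "returning best-seen parameters")
    return PersonalizationResult(params=ModelParameters.from_vector(best_p),
                                 rewards=np.array(rewards), steps=max_steps,
                                 converged=False, evaluations=max_steps)
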