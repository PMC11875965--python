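"""Weights-only actor and critic networks with analytic gradients.

The networks are deliberately tiny (one hidden layer of 100 units, no bias
terms), so forward passes and backpropagation are a handful of matrix
products written directly in numpy:

* actor  mu(S):   S (16) -> ReLU(W1 S) (100) -> tanh(W2 h) (22)
* critic Q(S,A):  ReLU(Ws S + Wa A) (100) -> Wo h (1, linear)

The critic applies its single nonlinearity after the elementwise addition of
the state and action branches. Gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ActorNetwork", "CriticNetwork", "soft_update", "SgdOptimizer",
           "AdamOptimizer", "make_optimizer"]

STATE_DIM = 16
ACTION_DIM = 22
HIDDEN = 100


def _init_layer(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    """Uniform [-1/sqrt(fan_in), 1/sqrt(fan_in)] initialization."""
    lim = 1.0 / np.sqrt(n_in)
    return rng.uniform(-lim, lim, size=(n_out, n_in))


class SgdOptimizer:
    """Plain stochastic gradient descent with optional L2 weight decay."""

    def __init__(self, lr: float, l2: float = 0.0):
        self.lr = lr
        self.l2 = l2

    def apply(self, weights: dict, grads: dict) -> None:
        for k, w in weights.items():
            w -= self.lr * (grads[k] + self.l2 * w)


class AdamOptimizer:
    """Adam with bias correction; one moment pair per weight matrix."""

    def __init__(self, lr: float, l2: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.l2 = l2
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def apply(self, weights: dict, grads: dict) -> None:
        self.t += 1
        for k, w in weights.items():
            g = grads[k] + self.l2 * w
            m = self._m.setdefault(k, np.zeros_like(w))
            v = self._v.setdefault(k, np.zeros_like(w))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, lr: float, l2: float = 0.0):
    if name == "adam":
        return AdamOptimizer(lr, l2)
    if name == "sgd":
        return SgdOptimizer(lr, l2)
    raise ValueError(f"unknown optimizer {name!r}")


class ActorNetwork:
    """Deterministic policy mu: state (16) -> action (22) in (-1, 1)."""

    def __init__(self, W1: np.ndarray, W2: np.ndarray):
        self.W1 = np.asarray(W1, dtype=float)
        self.W2 = np.asarray(W2, dtype=float)
        if self.W1.shape != (HIDDEN, STATE_DIM) or self.W2.shape != (ACTION_DIM, HIDDEN):
            raise ValueError("actor weight shapes must be (100,16) and (22,100)")

    @classmethod
    def init(cls, rng: np.random.Generator) -> "ActorNetwork":
        return cls(_init_layer(rng, HIDDEN, STATE_DIM),
                   _init_layer(rng, ACTION_DIM, HIDDEN))

    @classmethod
    def zeros(cls) -> "ActorNetwork":
        return cls(np.zeros((HIDDEN, STATE_DIM)), np.zeros((ACTION_DIM, HIDDEN)))

    def copy(self) -> "ActorNetwork":
        return ActorNetwork(self.W1.copy(), self.W2.copy())

    @property
    def weights(self) -> dict:
        return {"W1": self.W1, "W2": self.W2}

    def forward(self, S: np.ndarray) -> np.ndarray:
        """Action(s) for one state (16,) or a batch (N, 16)."""
        S = np.asarray(S, dtype=float)
        single = S.ndim == 1
        Sb = np.atleast_2d(S)
        if Sb.shape[1] != STATE_DIM:
            raise ValueError(f"state dimension must be {STATE_DIM}")
        H = np.maximum(Sb @ self.W1.T, 0.0)
        A = np.tanh(H @ self.W2.T)
        return A[0] if single else A

    __call__ = forward

    def policy_gradients(self, S: np.ndarray, dA: np.ndarray) -> dict:
        """Descent-direction gradients of ``-J`` for the policy objective
        ``J = (1/N) sum_i dA_i . mu(S_i)``.

        With ``dA`` holding the critic's action gradients dQ/dA this is the
        sampled deterministic policy gradient; applying the returned dict
        with any (descent) optimizer ascends J.
        """
        Sb = np.atleast_2d(np.asarray(S, dtype=float))
        dA = np.atleast_2d(np.asarray(dA, dtype=float))
        n = Sb.shape[0]
        pre1 = Sb @ self.W1.T
        H = np.maximum(pre1, 0.0)
        A = np.tanh(H @ self.W2.T)
        dpre2 = (dA / n) * (1.0 - A ** 2)
        gW2 = dpre2.T @ H
        dH = dpre2 @ self.W2
        dpre1 = dH * (pre1 > 0)
        gW1 = dpre1.T @ Sb
        return {"W1": -gW1, "W2": -gW2}

    def gradient_step(self, S: np.ndarray, dA: np.ndarray, lr: float,
                      l2: float = 0.0) -> None:
        """One plain-SGD ascent step on the policy objective (see
        :meth:`policy_gradients`)."""
        SgdOptimizer(lr, l2).apply(self.weights, self.policy_gradients(S, dA))


class CriticNetwork:
    """Action-value estimate Q(S, A): linear output, unbounded."""

    def __init__(self, Ws: np.ndarray, Wa: np.ndarray, Wo: np.ndarray):
        self.Ws = np.asarray(Ws, dtype=float)
        self.Wa = np.asarray(Wa, dtype=float)
        self.Wo = np.asarray(Wo, dtype=float)
        if (self.Ws.shape != (HIDDEN, STATE_DIM)
                or self.Wa.shape != (HIDDEN, ACTION_DIM)
                or self.Wo.shape != (1, HIDDEN)):
            raise ValueError("critic weight shapes must be (100,16), (100,22), (1,100)")

    @classmethod
    def init(cls, rng: np.random.Generator) -> "CriticNetwork":
        return cls(_init_layer(rng, HIDDEN, STATE_DIM),
                   _init_layer(rng, HIDDEN, ACTION_DIM),
                   _init_layer(rng, 1, HIDDEN))

    def copy(self) -> "CriticNetwork":
        return CriticNetwork(self.Ws.copy(), self.Wa.copy(), self.Wo.copy())

    @property
    def weights(self) -> dict:
        return {"Ws": self.Ws, "Wa": self.Wa, "Wo": self.Wo}

    def forward(self, S: np.ndarray, A: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        single = S.ndim == 1
        Sb, Ab = np.atleast_2d(S), np.atleast_2d(np.asarray(A, dtype=float))
        if Sb.shape[1] != STATE_DIM or Ab.shape[1] != ACTION_DIM:
            raise ValueError("bad state/action dimensions")
        z = Sb @ self.Ws.T + Ab @ self.Wa.T
        q = np.maximum(z, 0.0) @ self.Wo.T
        return float(q[0, 0]) if single else q[:, 0]

    __call__ = forward

    def action_gradient(self, S: np.ndarray, A: np.ndarray) -> np.ndarray:
        """dQ/dA for each (state, action) pair, shape (N, 22)."""
        Sb, Ab = np.atleast_2d(S), np.atleast_2d(A)
        z = Sb @ self.Ws.T + Ab @ self.Wa.T
        return ((z > 0) * self.Wo) @ self.Wa

    def td_gradients(self, S: np.ndarray, A: np.ndarray,
                     y: np.ndarray) -> tuple:
        """(loss, gradients) of the squared TD loss ``mean((y - Q)^2)``."""
        Sb, Ab = np.atleast_2d(S), np.atleast_2d(A)
        y = np.asarray(y, dtype=float)
        n = Sb.shape[0]
        z = Sb @ self.Ws.T + Ab @ self.Wa.T
        H = np.maximum(z, 0.0)
        q = (H @ self.Wo.T)[:, 0]
        err = q - y
        loss = float(np.mean(err ** 2))
        dq = (2.0 * err / n)[:, None]
        gWo = dq.T @ H
        dz = (dq @ self.Wo) * (z > 0)
        return loss, {"Ws": dz.T @ Sb, "Wa": dz.T @ Ab, "Wo": gWo}

    def td_step(self, S: np.ndarray, A: np.ndarray, y: np.ndarray, lr: float,
                l2: float = 0.0) -> float:
        """One plain-SGD step on the TD loss; returns the pre-step loss."""
        loss, grads = self.td_gradients(S, A, y)
        SgdOptimizer(lr, l2).apply(self.weights, grads)
        return loss


def soft_update(target, source, tau: float) -> None:
    """Move target weights toward source: theta' <- tau*theta + (1-tau)*theta'."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    tw, sw = target.weights, source.weights
    if tw.keys() != sw.keys():
        raise ValueError("mismatched networks")
    for k in tw:
        if tw[k].shape != sw[k].shape:
            raise ValueError(f"shape mismatch for {k}")
        tw[k] *= 1.0 - tau
        tw[k] += tau * sw[k]
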