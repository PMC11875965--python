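"""Replay buffer, exploration noise, DDPG pretraining and personalization."""

import numpy as np
import pytest

from emgmm.model import ModelParameters
from emgmm.networks import ActorNetwork, CriticNetwork
from emgmm.rl import (
    DdpgHyperparams,
    OuNoise,
    ReplayBuffer,
    Transition,
    ddpg_pretrain,
    personalize,
)
from emgmm.synthetic import generate_subject_cycles, sample_subject


def _transition(i):
    return Transition(np.full(16, float(i)), np.zeros(22), -float(i),
                      np.zeros(16))


class TestReplayBuffer:
    def test_fifo_eviction_at_capacity(self):
        buf = ReplayBuffer(capacity=4000)
        first = _transition(0)
        buf.add(first)
        for i in range(1, 4001):
            buf.add(_transition(i))
        assert len(buf) == 4000
        assert first not in buf
        # column arrays no longer hold the first state either
        assert not np.any(buf._S[:, 0] == 0.0)

    def test_sampling_without_replacement(self, rng):
        buf = ReplayBuffer(capacity=10)
        for i in range(10):
            buf.add(_transition(i))
        batch = buf.sample(rng, 10)
        ids = sorted(t.state[0] for t in batch)
        assert ids == list(range(10))
        with pytest.raises(ValueError):
            buf.sample(rng, 11)

    def test_array_view_consistent_with_objects(self, rng):
        buf = ReplayBuffer(capacity=5)
        for i in range(8):
            buf.add(_transition(i))
        S, A, r, S1 = buf.sample_arrays(rng, 5)
        assert sorted(S[:, 0]) == [3.0, 4.0, 5.0, 6.0, 7.0]
        assert sorted(-r) == [3.0, 4.0, 5.0, 6.0, 7.0]


class TestOuNoise:
    def test_zero_std_is_silent(self, rng):
        noise = OuNoise(sigma=0.0)
        for _ in range(10):
            assert np.all(noise.step(rng) == 0.0)

    def test_seeded_reproducibility(self):
        a = OuNoise().step(np.random.default_rng(3))
        b = OuNoise().step(np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_std_decays_multiplicatively(self, rng):
        noise = OuNoise(sigma=0.30, decay=1e-4)
        noise.step(rng)
        assert noise.sigma == pytest.approx(0.30 * (1 - 1e-4))

    def test_mean_reversion_without_noise(self, rng):
        noise = OuNoise(sigma=0.0, theta=0.15)
        noise.x[:] = 1.0
        noise.step(rng)
        assert np.allclose(noise.x, 0.85)


@pytest.fixture(scope="module")
def two_subject_pool():
    subs = [sample_subject(seed=s, rho=0.2) for s in (31, 32)]
    return [generate_subject_cycles(s, 3) for s in subs]


class TestPretrain:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            ddpg_pretrain([])
        with pytest.raises(ValueError):
            ddpg_pretrain([[]])

    def test_zero_actor_without_exploration_is_inert(self, two_subject_pool):
        """No exploration noise and a zero policy: actions stay zero, the
        parameters never move, and every reward within an episode is equal
        (a single repeated cycle)."""
        hp = DdpgHyperparams(episodes=6, ou_std=0.0, minibatch=10)
        res = ddpg_pretrain([c[:1] for c in two_subject_pool], hp, seed=0,
                            actor=ActorNetwork.zeros(),
                            critic=CriticNetwork(np.zeros((100, 16)),
                                                 np.zeros((100, 22)),
                                                 np.zeros((1, 100))))
        assert np.all(res.actor.W1 == 0.0) and np.all(res.actor.W2 == 0.0)
        # each episode's mean reward equals the (constant) per-step reward
        for t in res.buffer.sample(np.random.default_rng(0), 10):
            assert np.all(t.action == 0.0)
            assert np.array_equal(t.state, t.next_state)

    def test_buffer_never_exceeds_capacity(self, two_subject_pool):
        hp = DdpgHyperparams(episodes=4, buffer_size=30, minibatch=10)
        res = ddpg_pretrain(two_subject_pool, hp, seed=1)
        assert len(res.buffer) <= 30

    def test_learning_progress_on_small_pool(self, two_subject_pool):
        """Across seeds, later episodes should collect more reward than the
        first ones (majority vote over 3 seeds)."""
        wins = 0
        for seed in (0, 1, 2):
            res = ddpg_pretrain(two_subject_pool,
                                DdpgHyperparams(episodes=60), seed=seed)
            er = res.episode_rewards
            wins += er[-10:].mean() > er[:10].mean()
        assert wins >= 2

    def test_parameters_stay_in_bounds_throughout(self, two_subject_pool):
        bl, bu = ModelParameters.bounds_vectors()
        hp = DdpgHyperparams(episodes=3, ou_std=1.0)
        res = ddpg_pretrain(two_subject_pool, hp, seed=5)
        for t in res.buffer.sample(np.random.default_rng(0), len(res.buffer)):
            assert np.all(np.abs(t.action) <= 1.0)


class TestPersonalize:
    def test_zero_policy_stops_at_step_four_unchanged(self, generic, cycles):
        res = personalize(ActorNetwork.zeros(), [cycles[0]], generic=generic)
        assert res.steps == 4
        assert res.converged
        assert np.array_equal(res.params.to_vector(), generic.to_vector())

    def test_deterministic(self, two_subject_pool, cycles):
        policy = ddpg_pretrain(two_subject_pool,
                               DdpgHyperparams(episodes=20), seed=0).actor
        a = personalize(policy, cycles[:3])
        b = personalize(policy, cycles[:3])
        assert np.array_equal(a.params.to_vector(), b.params.to_vector())
        assert np.array_equal(a.rewards, b.rewards)
        assert a.steps == b.steps

    def test_cap_returns_best_with_warning(self, cycles):
        with pytest.warns(UserWarning, match="step cap"):
            res = personalize(ActorNetwork.zeros(), [cycles[0]], max_steps=3)
        assert not res.converged
        assert res.steps == 3

    def test_policy_improves_reward_over_seeds(self, two_subject_pool):
        """A policy pretrained on two subjects should not degrade a third:
        final reward >= initial reward in most seeds."""
        wins = 0
        for seed in (0, 1, 2):
            policy = ddpg_pretrain(two_subject_pool,
                                   DdpgHyperparams(episodes=60),
                                   seed=seed).actor
            target = sample_subject(seed=90 + seed, rho=0.2)
            res = personalize(policy, generate_subject_cycles(target, 3))
            wins += res.rewards[-1] >= res.rewards[0]
        assert wins >= 2

    def test_requires_cycles(self):
        with pytest.raises(ValueError):
            personalize(ActorNetwork.zeros(), [])
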