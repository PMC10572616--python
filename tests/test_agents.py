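"""Q-learning machinery: schedules, targets, projection, replay, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucorl.agents import (
    AgentConfig,
    DQNAgent,
    PrioritizedBuffer,
    ReplayBuffer,
    Transition,
    categorical_project,
    dueling_aggregate,
    epsilon,
    per_sample,
    select_action,
    td_target_ddqn,
    td_target_dqn,
    train,
)


def _transition(rng, obs_dim=4, n_actions=2, reward=0.0, done=False):
    return Transition(rng.standard_normal(obs_dim), int(rng.integers(n_actions)),
                      reward, rng.standard_normal(obs_dim), done, 0.99)


class TestEpsilonSchedule:
    def test_boundary_values(self):
        assert epsilon(0) == pytest.approx(1.0)
        assert epsilon(1e9) == pytest.approx(0.01)
        assert epsilon(3e4) == pytest.approx(0.01 + 0.99 * np.exp(-1), abs=1e-6)
        assert epsilon(3e4) == pytest.approx(0.3742, abs=1e-4)

    def test_strictly_decreasing_and_bounded(self):
        ts = np.linspace(0, 2e5, 1000)
        vals = [epsilon(t) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.01 <= v <= 1.0 for v in vals)

    def test_schedule_average_over_training(self):
        """Numeric average of eps(t) over 1e5 steps is ~0.30 (not the 50%
        sometimes quoted loosely for this schedule)."""
        avg = np.mean([epsilon(t) for t in range(100_000)])
        assert avg == pytest.approx(0.2964, abs=0.005)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            epsilon(-1)


class TestSelectAction:
    def test_greedy_argmax(self):
        rng = np.random.default_rng(0)
        assert select_action(np.array([1.0, 3.0, 2.0]), 0.0, rng) == 1

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert select_action(np.array([2.0, 2.0, 1.0]), 0.0, rng) == 0

    def test_uniform_at_full_exploration(self):
        rng = np.random.default_rng(1)
        counts = np.bincount(
            [select_action(np.array([9.0, 0.0, 0.0]), 1.0, rng) for _ in range(10_000)],
            minlength=3) / 10_000
        assert np.all((0.30 <= counts) & (counts <= 0.37))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            select_action(np.array([np.nan, 1.0]), 0.0, np.random.default_rng(0))


class TestTDTargets:
    def test_terminal_truncates(self):
        y = td_target_dqn(np.array([1.0]), np.array([True]),
                          np.array([[5.0, 7.0]]), 0.99)
        assert y == pytest.approx([1.0])

    def test_bootstrap_arithmetic(self):
        y = td_target_dqn(np.array([0.5]), np.array([False]),
                          np.array([[1.0, 2.0]]), 0.99)
        assert y == pytest.approx([0.5 + 0.99 * 2.0])

    def test_myopic_limit(self):
        rng = np.random.default_rng(2)
        r = rng.standard_normal(8)
        q = rng.standard_normal((8, 3))
        assert td_target_dqn(r, np.zeros(8, bool), q, 0.0) == pytest.approx(r)

    def test_ddqn_equals_dqn_when_nets_agree(self):
        rng = np.random.default_rng(3)
        q = rng.standard_normal((16, 4))
        r = rng.standard_normal(16)
        dones = rng.uniform(size=16) < 0.3
        assert td_target_ddqn(r, dones, q, q, 0.99) == pytest.approx(
            td_target_dqn(r, dones, q, 0.99))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_ddqn_never_exceeds_dqn(self, seed):
        """Selecting the bootstrap action with a different net can only
        lower (or match) the max-evaluated target."""
        rng = np.random.default_rng(seed)
        q_online = rng.standard_normal((8, 3))
        q_target = rng.standard_normal((8, 3))
        r = rng.standard_normal(8)
        dones = np.zeros(8, bool)
        y_ddqn = td_target_ddqn(r, dones, q_online, q_target, 0.99)
        y_dqn = td_target_dqn(r, dones, q_target, 0.99)
        assert np.all(y_ddqn <= y_dqn + 1e-12)


class TestDuelingAggregate:
    def test_hand_arithmetic(self):
        q = dueling_aggregate(np.array([5.0]), np.array([[1.0, -1.0]]))
        assert np.allclose(q, [[6.0, 4.0]])

    def test_constant_advantage_shift_invariant(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(6)
        a = rng.standard_normal((6, 3))
        assert dueling_aggregate(v, a) == pytest.approx(dueling_aggregate(v, a + 7.5))

    def test_equal_advantages_give_value(self):
        q = dueling_aggregate(np.array([2.0]), np.array([[3.0, 3.0, 3.0]]))
        assert np.allclose(q, [[2.0, 2.0, 2.0]])


class TestCategoricalProjection:
    def setup_method(self):
        self.atoms = np.linspace(-10.0, 10.0, 21)

    def test_terminal_exact_atom_is_delta(self):
        out = categorical_project(np.array([3.0]), np.array([True]),
                                  np.full((1, 21), 1 / 21), 0.99, self.atoms)
        expected = np.zeros(21)
        expected[np.argmin(np.abs(self.atoms - 3.0))] = 1.0
        assert out[0] == pytest.approx(expected)

    def test_terminal_below_support_clips_to_lowest_atom(self):
        out = categorical_project(np.array([-1000.0]), np.array([True]),
                                  np.full((1, 21), 1 / 21), 0.99, self.atoms)
        assert out[0, 0] == pytest.approx(1.0)

    def test_identity_backup_keeps_uniform(self):
        """r=0, gamma=1 maps every atom onto itself: uniform stays uniform."""
        uniform = np.full((1, 21), 1 / 21)
        out = categorical_project(np.array([0.0]), np.array([False]),
                                  uniform, 1.0, self.atoms)
        assert out == pytest.approx(uniform)

    def test_brute_force_oracle(self):
        """Mass-splitting checked against an explicit per-atom loop."""
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(21), size=3)
        r = np.array([1.7, -4.2, 900.0])
        dones = np.array([False, False, False])
        gamma = 0.9
        out = categorical_project(r, dones, probs, gamma, self.atoms)
        dz = self.atoms[1] - self.atoms[0]
        for i in range(3):
            expected = np.zeros(21)
            for j, z in enumerate(self.atoms):
                tz = np.clip(r[i] + gamma * z, self.atoms[0], self.atoms[-1])
                pos = (tz - self.atoms[0]) / dz
                lo = int(np.floor(pos))
                hi = min(lo + 1, 20)
                expected[lo] += probs[i, j] * (1 - (pos - lo))
                expected[hi] += probs[i, j] * (pos - lo)
            assert out[i] == pytest.approx(expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_mass_conservation(self, seed):
        """Projection conserves probability mass for arbitrary rewards
        including the -1000 punishment."""
        rng = np.random.default_rng(seed)
        n = 5
        probs = rng.dirichlet(np.ones(21), size=n)
        r = rng.choice([-1000.0, 0.0, 1.0, 500.0], size=n)
        dones = rng.uniform(size=n) < 0.5
        out = categorical_project(r, dones, probs, 0.99, self.atoms)
        assert np.all(out >= 0)
        assert out.sum(axis=1) == pytest.approx(np.ones(n), abs=1e-6)


class TestReplayBuffers:
    def test_fifo_eviction_at_capacity(self):
        rng = np.random.default_rng(6)
        buf = ReplayBuffer(capacity=5)
        trs = [_transition(rng, reward=float(i)) for i in range(8)]
        for t in trs:
            buf.push(t)
        assert len(buf) == 5
        stored = {t.reward for t in buf._storage}
        assert stored == {3.0, 4.0, 5.0, 6.0, 7.0}

    def test_uniform_sampling_is_uniform(self):
        """Chi-square test on the empirical sampling frequencies."""
        from scipy.stats import chisquare
        rng = np.random.default_rng(7)
        buf = ReplayBuffer(capacity=20)
        for i in range(20):
            buf.push(_transition(rng, reward=float(i)))
        counts = np.zeros(20)
        for _ in range(5000):
            _, idx, w = buf.sample(20, rng)
            assert np.all(w == 1.0)
            counts += np.bincount(idx, minlength=20)
        assert chisquare(counts).pvalue > 1e-4

    def test_sample_requires_enough_transitions(self):
        buf = ReplayBuffer(capacity=10)
        with pytest.raises(RuntimeError):
            buf.sample(1, np.random.default_rng(0))

    def test_per_uniform_priorities_give_unit_weights(self):
        rng = np.random.default_rng(8)
        buf = PrioritizedBuffer(capacity=10, alpha=1.0)
        for i in range(10):
            buf.push(_transition(rng))
        _, _, w = per_sample(buf, 8, rng, beta=1.0)
        assert np.allclose(w, 1.0)

    def test_per_high_priority_dominates(self):
        rng = np.random.default_rng(9)
        buf = PrioritizedBuffer(capacity=10, alpha=1.0)
        for i in range(10):
            buf.push(_transition(rng))
        buf.update_priorities(np.arange(10), np.full(10, 1e-3))
        buf.update_priorities([4], [1000.0])
        hits = []
        for _ in range(500):
            _, idx, _ = buf.sample(10, rng, beta=0.0)
            hits.append(np.mean(idx == 4))
        assert np.mean(hits) > 0.98

    def test_per_weight_ratio_hand_arithmetic(self):
        """Two transitions, priorities 3 and 1, alpha=1, beta=1: raw weights
        are proportional to 1/3 and 1, ratio 1:3 before normalization."""
        rng = np.random.default_rng(10)
        buf = PrioritizedBuffer(capacity=2, alpha=1.0)
        buf.push(_transition(rng))
        buf.push(_transition(rng))
        buf.update_priorities([0, 1], [3.0 - buf.min_priority, 1.0 - buf.min_priority])
        for _ in range(50):
            _, idx, w = buf.sample(2, rng, beta=1.0)
            if set(idx) == {0, 1}:
                ratio = w[list(idx).index(0)] / w[list(idx).index(1)]
                assert ratio == pytest.approx(1.0 / 3.0)
                break
        else:
            pytest.fail("never sampled both transitions")

    def test_new_transitions_enter_at_max_priority(self):
        rng = np.random.default_rng(11)
        buf = PrioritizedBuffer(capacity=5)
        buf.push(_transition(rng))
        buf.update_priorities([0], [50.0])
        buf.push(_transition(rng))
        assert buf._priorities[1] == buf._max_priority


class TestAgentConfig:
    def test_variant_flags_rainbow_enables_everything(self):
        cfg = AgentConfig(variant="rainbow")
        assert cfg.double and cfg.dueling and cfg.noisy
        assert cfg.prioritized and cfg.categorical
        assert cfg.multi_step == 3

    @pytest.mark.parametrize("variant, dueling", [
        ("dqn", False), ("ddqn", False), ("dueling_dqn", True),
        ("dueling_ddqn", True), ("per_dqn", True), ("noisy_dqn", True),
    ])
    def test_architecture_assignment(self, variant, dueling):
        assert AgentConfig(variant=variant).dueling is dueling

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AgentConfig(variant="sarsa")
        with pytest.raises(ValueError):
            AgentConfig(discount=1.0)
        with pytest.raises(ValueError):
            AgentConfig(batch_size=200, buffer_capacity=100)


class TestTrainStep:
    def _warm_agent(self, variant, seed=0, n=64):
        """Buffer of terminal transitions: the targets are fixed values
        (deltas, for distributional variants), so the loss has a zero
        floor and repeated updates must drive it down."""
        rng = np.random.default_rng(seed)
        cfg = AgentConfig(variant=variant, batch_size=16, buffer_capacity=256,
                          hidden=16, training_steps=1000)
        agent = DQNAgent(obs_dim=4, n_actions=2, config=cfg, seed=seed)
        for _ in range(n):
            agent.buffer.push(_transition(rng, reward=float(rng.uniform(-1, 1)),
                                          done=True))
        return agent

    @pytest.mark.parametrize("variant", ["dqn", "dueling_ddqn", "per_dqn",
                                         "noisy_dqn", "categorical_dqn", "rainbow"])
    def test_loss_finite_and_decreasing_on_fixed_buffer(self, variant):
        """Repeated updates on a fixed replay set drive the loss down."""
        agent = self._warm_agent(variant)
        first = [agent.train_step() for _ in range(50)]
        losses = [agent.train_step() for _ in range(350)]
        assert np.all(np.isfinite(losses))
        assert np.mean(losses[-50:]) < np.mean(first)

    def test_target_net_frozen_between_syncs(self):
        agent = self._warm_agent("dqn")
        before = [p.data.copy() for p in agent.target.parameters()]
        for _ in range(10):  # < target_update_period
            agent.train_step()
        for b, p in zip(before, agent.target.parameters()):
            assert np.array_equal(b, p.data)
        online = [p.data for p in agent.online.parameters()]
        assert any(not np.array_equal(b, o) for b, o in zip(before, online))

    def test_empty_buffer_raises(self):
        cfg = AgentConfig(variant="dqn", batch_size=16, hidden=8)
        agent = DQNAgent(4, 2, cfg, seed=0)
        with pytest.raises(RuntimeError):
            agent.train_step()


class TestTrainingLoop:
    def test_same_seed_identical_logs(self, toy_env_cls):
        cfg = AgentConfig(variant="dqn", hidden=8, training_steps=300,
                          learning_starts=50, batch_size=16, buffer_capacity=500)
        _, log_a = train(toy_env_cls(seed=5), cfg, seed=11)
        _, log_b = train(toy_env_cls(seed=5), cfg, seed=11)
        assert log_a == log_b

    @pytest.mark.parametrize("variant", ["dqn", "ddqn"])
    def test_tabular_policy_recovery(self, toy_env_cls, variant):
        """On the 5-state chain, the learned greedy policy matches
        brute-force value iteration wherever the optimum is unique."""
        cfg = AgentConfig(variant=variant, discount=0.9, hidden=24,
                          training_steps=4000, learning_starts=200,
                          batch_size=32, buffer_capacity=5000,
                          target_update_period=200, eps_decay=1000.0)
        agent, _ = train(toy_env_cls(seed=3), cfg, seed=7)
        q_star = toy_env_cls.optimal_q(discount=0.9)
        for s in range(toy_env_cls.n_states):
            if abs(q_star[s, 0] - q_star[s, 1]) < 1e-6:
                continue  # symmetric tie: either action is optimal
            learned = agent.act_greedy(np.eye(toy_env_cls.n_states)[s])
            assert learned == int(np.argmax(q_star[s])), f"state {s}"

    def test_checkpoint_round_trip(self, toy_env_cls, tmp_path):
        cfg = AgentConfig(variant="dueling_dqn", hidden=8, training_steps=120,
                          learning_starts=40, batch_size=16)
        agent, _ = train(toy_env_cls(seed=1), cfg, seed=2)
        path = tmp_path / "agent.npz"
        agent.save(path)
        loaded = DQNAgent.load(path)
        obs = np.eye(5)[3]
        assert loaded.act_greedy(obs) == agent.act_greedy(obs)
        assert np.allclose(loaded.q_values(obs), agent.q_values(obs))
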