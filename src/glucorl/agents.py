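"""Value-based deep Q-learning controllers and their training loop.

Seven variants are provided, all sharing one agent skeleton:

========================  =====================================================
``dqn``                   4-layer fully connected net (64 units), TD(0) target
``ddqn``                  double Q-learning: online net selects, target net
                          evaluates the bootstrap action
``dueling_dqn``           two separate 4-layer blocks for state value and
                          advantages, Q = V + A - mean(A)
``dueling_ddqn``          dueling architecture + double targets
``per_dqn``               dueling-style net + prioritized experience replay
``noisy_dqn``             dueling-style net with factorized-noise layers
``categorical_dqn``       distributional (51-atom) head; 4-layer net whose
                          last two layers are noisy
``rainbow``               double + dueling + PER + noisy + categorical +
                          3-step returns
========================  =====================================================

Exploration is decaying epsilon-greedy, eps(t) = epsF + (eps0 - epsF)
exp(-t / eta) with eps0 = 1, epsF = 0.01, eta = 3e4, applied to every
variant (noisy variants explore through their parameter noise as well).
Non-distributional variants minimize the mean squared TD error with Adam
(lr 1e-3); distributional variants use the cross-entropy to the projected
target distribution, since a squared error between the projected and
predicted probability vectors does not define the distributional Bellman
update. Evaluation is greedy with noise switched off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from glucorl.nn import MLP, Adam, Linear, NoisyLinear, Param, ReLU

__all__ = [
    "VARIANTS",
    "AgentConfig",
    "Transition",
    "ReplayBuffer",
    "PrioritizedBuffer",
    "epsilon",
    "select_action",
    "td_target_dqn",
    "td_target_ddqn",
    "dueling_aggregate",
    "categorical_project",
    "per_sample",
    "DQNAgent",
    "train",
    "TrainingDivergedError",
]

VARIANTS = (
    "dqn", "ddqn", "dueling_dqn", "dueling_ddqn",
    "per_dqn", "noisy_dqn", "categorical_dqn", "rainbow",
)


class TrainingDivergedError(RuntimeError):
    """Raised when a training step produces a non-finite loss."""


@dataclass(frozen=True)
class AgentConfig:
    """Hyperparameters of one controller variant.

    Defaults follow the benchmark protocol: discount 0.99, Adam at 1e-3,
    batch 128, replay capacity 1e5, 1e5 training steps, epsilon schedule
    (1.0 -> 0.01, decay 3e4). PER and categorical constants are the
    customary ones from the original algorithms.
    """

    variant: str = "dqn"
    discount: float = 0.99
    learning_rate: float = 1e-3
    batch_size: int = 128
    buffer_capacity: int = 100_000
    training_steps: int = 100_000
    target_update_period: int = 1_000
    learning_starts: int = 1_000
    eps0: float = 1.0
    eps_final: float = 0.01
    eps_decay: float = 3e4
    hidden: int = 64
    per_alpha: float = 0.6
    per_beta0: float = 0.4
    per_beta_final: float = 1.0
    per_epsilon: float = 1e-6
    n_atoms: int = 51
    v_min: float = -1000.0
    v_max: float = 10.0
    n_step: int | None = None  # None -> 3 for rainbow, 1 otherwise

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if not 0.0 < self.discount < 1.0:
            raise ValueError("discount must lie in (0, 1)")
        if self.batch_size > self.buffer_capacity:
            raise ValueError("batch size cannot exceed buffer capacity")

    # derived structural flags -------------------------------------------------
    @property
    def double(self) -> bool:
        return self.variant in ("ddqn", "dueling_ddqn", "rainbow")

    @property
    def dueling(self) -> bool:
        return self.variant in ("dueling_dqn", "dueling_ddqn", "per_dqn",
                                "noisy_dqn", "rainbow")

    @property
    def noisy(self) -> bool:
        return self.variant in ("noisy_dqn", "categorical_dqn", "rainbow")

    @property
    def prioritized(self) -> bool:
        return self.variant in ("per_dqn", "rainbow")

    @property
    def categorical(self) -> bool:
        return self.variant in ("categorical_dqn", "rainbow")

    @property
    def multi_step(self) -> int:
        if self.n_step is not None:
            return self.n_step
        return 3 if self.variant == "rainbow" else 1


@dataclass(frozen=True)
class Transition:
    """One replay record; ``discount`` is gamma^n of the n-step return."""

    observation: np.ndarray
    action: int
    reward: float
    next_observation: np.ndarray
    done: bool
    discount: float


# ---------------------------------------------------------------------------
# schedules and target rules (pure functions)

def epsilon(t: float, eps0: float = 1.0, eps_final: float = 0.01,
            decay: float = 3e4) -> float:
    """Exploration probability eps(t) = epsF + (eps0 - epsF) exp(-t/decay)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return eps_final + (eps0 - eps_final) * np.exp(-t / decay)


def select_action(q_values: np.ndarray, eps: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy over a 1-D Q-value vector; greedy ties break to the
    lowest index."""
    q_values = np.asarray(q_values, dtype=float)
    if not np.all(np.isfinite(q_values)):
        raise ValueError("q_values must be finite")
    if rng.uniform() < eps:
        return int(rng.integers(len(q_values)))
    return int(np.argmax(q_values))


def td_target_dqn(rewards: np.ndarray, dones: np.ndarray,
                  q_next_target: np.ndarray, discount) -> np.ndarray:
    """y = r + gamma * max_a Q_target(s', a), truncated at terminals."""
    boot = np.max(q_next_target, axis=1)
    return np.asarray(rewards) + np.asarray(discount) * boot * (~np.asarray(dones))


def td_target_ddqn(rewards: np.ndarray, dones: np.ndarray,
                   q_next_online: np.ndarray, q_next_target: np.ndarray,
                   discount) -> np.ndarray:
    """Double target: the online net picks the bootstrap action, the target
    net scores it."""
    sel = np.argmax(q_next_online, axis=1)
    boot = q_next_target[np.arange(len(sel)), sel]
    return np.asarray(rewards) + np.asarray(discount) * boot * (~np.asarray(dones))


def dueling_aggregate(value: np.ndarray, advantages: np.ndarray) -> np.ndarray:
    """Q(s, a) = V(s) + A(s, a) - mean_a A(s, a).

    Subtracting the mean advantage removes the V/A ambiguity (adding any
    constant to all advantages leaves Q unchanged).
    """
    value = np.asarray(value, dtype=float)
    advantages = np.asarray(advantages, dtype=float)
    return value[..., None] + advantages - advantages.mean(axis=-1, keepdims=True)


def categorical_project(rewards: np.ndarray, dones: np.ndarray,
                        next_probs: np.ndarray, discount,
                        atoms: np.ndarray) -> np.ndarray:
    """Distributional Bellman backup onto a fixed atom grid.

    Each atom z_j maps to clip(r + gamma * z_j, v_min, v_max) (terminal
    transitions collapse onto clip(r, ...)), and its probability mass is
    split linearly between the two neighbouring grid atoms. Probability
    mass is conserved exactly.
    """
    rewards = np.asarray(rewards, dtype=float)
    dones = np.asarray(dones, dtype=bool)
    next_probs = np.asarray(next_probs, dtype=float)
    atoms = np.asarray(atoms, dtype=float)
    n, k = next_probs.shape
    v_min, v_max = atoms[0], atoms[-1]
    dz = (v_max - v_min) / (k - 1)
    gamma = np.broadcast_to(np.asarray(discount, dtype=float), (n,))

    tz = rewards[:, None] + np.where(dones[:, None], 0.0, gamma[:, None] * atoms[None, :])
    tz = np.clip(tz, v_min, v_max)
    # terminal rows carry a delta at clip(r): give it the whole row's mass
    probs = np.where(dones[:, None], np.full((n, k), 1.0 / k), next_probs)

    pos = (tz - v_min) / dz
    lower = np.floor(pos).astype(int)
    upper = np.minimum(lower + 1, k - 1)
    frac = pos - lower

    out = np.zeros((n, k))
    rows = np.repeat(np.arange(n), k)
    np.add.at(out, (rows, lower.ravel()), (probs * (1.0 - frac)).ravel())
    np.add.at(out, (rows, upper.ravel()), (probs * frac).ravel())
    return out


def per_sample(buffer: "PrioritizedBuffer", batch_size: int,
               rng: np.random.Generator, beta: float = 0.4):
    """Priority-proportional sampling with importance weights.

    Index i is drawn with probability p_i^alpha / sum_j p_j^alpha; weights
    (N P(i))^-beta are normalized so the largest weight in the batch is 1.
    """
    return buffer.sample(batch_size, rng, beta)


# ---------------------------------------------------------------------------
# replay buffers

class ReplayBuffer:
    """Uniform FIFO replay buffer."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._storage: list[Transition] = []
        self._cursor = 0

    def __len__(self) -> int:
        return len(self._storage)

    def push(self, transition: Transition) -> None:
        if len(self._storage) < self.capacity:
            self._storage.append(transition)
        else:
            self._storage[self._cursor] = transition
        self._cursor = (self._cursor + 1) % self.capacity

    def sample(self, batch_size: int, rng: np.random.Generator):
        if len(self._storage) < batch_size:
            raise RuntimeError("buffer holds fewer transitions than the batch size")
        idx = rng.integers(len(self._storage), size=batch_size)
        batch = [self._storage[i] for i in idx]
        return batch, idx, np.ones(batch_size)

    def update_priorities(self, indices, priorities) -> None:  # uniform: no-op
        pass


class PrioritizedBuffer(ReplayBuffer):
    """Proportional prioritized replay.

    New transitions enter with the current maximal priority so every
    experience is replayed at least with a fresh chance; priorities are
    refreshed from the TD errors after each update.
    """

    def __init__(self, capacity: int, alpha: float = 0.6, min_priority: float = 1e-6):
        super().__init__(capacity)
        self.alpha = alpha
        self.min_priority = min_priority
        self._priorities = np.zeros(capacity)
        self._max_priority = 1.0

    def push(self, transition: Transition) -> None:
        slot = len(self._storage) if len(self._storage) < self.capacity else self._cursor
        super().push(transition)
        self._priorities[slot] = self._max_priority

    def sample(self, batch_size: int, rng: np.random.Generator, beta: float = 0.4):
        n = len(self._storage)
        if n == 0:
            raise RuntimeError("buffer is empty")
        if n < batch_size:
            raise RuntimeError("buffer holds fewer transitions than the batch size")
        scaled = self._priorities[:n] ** self.alpha
        probs = scaled / scaled.sum()
        idx = rng.choice(n, size=batch_size, p=probs)
        weights = (n * probs[idx]) ** (-beta)
        weights /= weights.max()
        batch = [self._storage[i] for i in idx]
        return batch, idx, weights

    def update_priorities(self, indices, priorities) -> None:
        priorities = np.abs(np.asarray(priorities, dtype=float)) + self.min_priority
        self._priorities[np.asarray(indices)] = priorities
        self._max_priority = max(self._max_priority, float(priorities.max()))


# ---------------------------------------------------------------------------
# network architectures

class QNetwork:
    """Plain 4-layer net: in -> 64 -> 64 -> 64 -> n_actions."""

    def __init__(self, obs_dim: int, n_actions: int, hidden: int,
                 rng: np.random.Generator, noisy: bool = False):
        h = hidden
        self.net = MLP([obs_dim, h, h, h, n_actions], rng,
                       noisy_from=0 if noisy else None)
        self.n_actions = n_actions

    def q_values(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward_from_q(self, grad_q: np.ndarray) -> None:
        self.net.backward(grad_q)

    def parameters(self) -> list[Param]:
        return self.net.parameters()

    def noisy_layers(self) -> list[NoisyLinear]:
        return self.net.noisy_layers()


class DuelingNetwork:
    """Two fully separate 4-layer blocks ending in value and advantage
    streams, combined as Q = V + A - mean(A)."""

    def __init__(self, obs_dim: int, n_actions: int, hidden: int,
                 rng: np.random.Generator, noisy: bool = False):
        h = hidden
        nf = 0 if noisy else None
        self.value = MLP([obs_dim, h, h, h, 1], rng, noisy_from=nf)
        self.advantage = MLP([obs_dim, h, h, h, n_actions], rng, noisy_from=nf)
        self.n_actions = n_actions

    def q_values(self, x: np.ndarray) -> np.ndarray:
        v = self.value.forward(x)[:, 0]
        a = self.advantage.forward(x)
        return dueling_aggregate(v, a)

    def backward_from_q(self, grad_q: np.ndarray) -> None:
        grad_a = grad_q - grad_q.mean(axis=1, keepdims=True)
        grad_v = grad_q.sum(axis=1, keepdims=True)
        self.advantage.backward(grad_a)
        self.value.backward(grad_v)

    def parameters(self) -> list[Param]:
        return self.value.parameters() + self.advantage.parameters()

    def noisy_layers(self) -> list[NoisyLinear]:
        return self.value.noisy_layers() + self.advantage.noisy_layers()


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class CategoricalNetwork:
    """Distributional head: 4-layer net, the last two layers noisy, output
    n_actions x n_atoms logits softmaxed over atoms."""

    def __init__(self, obs_dim: int, n_actions: int, hidden: int,
                 rng: np.random.Generator, atoms: np.ndarray):
        h = hidden
        self.atoms = atoms
        self.n_actions = n_actions
        self.n_atoms = len(atoms)
        self.net = MLP([obs_dim, h, h, h, n_actions * self.n_atoms], rng, noisy_from=2)
        self._probs: np.ndarray | None = None

    def distributions(self, x: np.ndarray) -> np.ndarray:
        logits = self.net.forward(x).reshape(len(x), self.n_actions, self.n_atoms)
        self._probs = _softmax(logits)
        return self._probs

    def q_values(self, x: np.ndarray) -> np.ndarray:
        return self.distributions(x) @ self.atoms

    def backward_from_logits(self, grad_logits: np.ndarray) -> None:
        self.net.backward(grad_logits.reshape(len(grad_logits), -1))

    def parameters(self) -> list[Param]:
        return self.net.parameters()

    def noisy_layers(self) -> list[NoisyLinear]:
        return self.net.noisy_layers()


class RainbowNetwork:
    """Shared linear input layer, then two 3-noisy-layer blocks producing
    value and advantage atom logits, dueling-combined before the softmax."""

    def __init__(self, obs_dim: int, n_actions: int, hidden: int,
                 rng: np.random.Generator, atoms: np.ndarray):
        h = hidden
        self.atoms = atoms
        self.n_actions = n_actions
        self.n_atoms = len(atoms)
        self.input = Linear(obs_dim, h, rng)
        self.input_act = ReLU()
        self.value = MLP([h, h, h, self.n_atoms], rng, noisy_from=0)
        self.advantage = MLP([h, h, h, n_actions * self.n_atoms], rng, noisy_from=0)

    def distributions(self, x: np.ndarray) -> np.ndarray:
        trunk = self.input_act.forward(self.input.forward(x))
        v = self.value.forward(trunk)[:, None, :]
        a = self.advantage.forward(trunk).reshape(len(x), self.n_actions, self.n_atoms)
        logits = v + a - a.mean(axis=1, keepdims=True)
        return _softmax(logits)

    def q_values(self, x: np.ndarray) -> np.ndarray:
        return self.distributions(x) @ self.atoms

    def backward_from_logits(self, grad_logits: np.ndarray) -> None:
        grad_a = grad_logits - grad_logits.mean(axis=1, keepdims=True)
        grad_v = grad_logits.sum(axis=1)
        g_trunk = self.advantage.backward(grad_a.reshape(len(grad_a), -1))
        g_trunk = g_trunk + self.value.backward(grad_v)
        self.input.backward(self.input_act.backward(g_trunk))

    def parameters(self) -> list[Param]:
        return (self.input.parameters() + self.value.parameters()
                + self.advantage.parameters())

    def noisy_layers(self) -> list[NoisyLinear]:
        return self.value.noisy_layers() + self.advantage.noisy_layers()


def _build_network(config: AgentConfig, obs_dim: int, n_actions: int,
                   rng: np.random.Generator):
    if config.variant == "rainbow":
        atoms = np.linspace(config.v_min, config.v_max, config.n_atoms)
        return RainbowNetwork(obs_dim, n_actions, config.hidden, rng, atoms)
    if config.variant == "categorical_dqn":
        atoms = np.linspace(config.v_min, config.v_max, config.n_atoms)
        return CategoricalNetwork(obs_dim, n_actions, config.hidden, rng, atoms)
    if config.dueling:
        return DuelingNetwork(obs_dim, n_actions, config.hidden, rng,
                              noisy=config.noisy)
    return QNetwork(obs_dim, n_actions, config.hidden, rng, noisy=config.noisy)


# ---------------------------------------------------------------------------
# the agent

class DQNAgent:
    """One value-based controller: online net, target net, replay, Adam."""

    def __init__(self, obs_dim: int, n_actions: int, config: AgentConfig, seed: int):
        self.config = config
        self.obs_dim = obs_dim
        self.n_actions = n_actions
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        init_ss, self._noise_rng, self._explore_rng, self._buffer_rng = (
            np.random.default_rng(s) for s in ss.spawn(4))
        # target net built from the same init stream state, then overwritten
        init_rng = init_ss
        self.online = _build_network(config, obs_dim, n_actions, init_rng)
        self.target = _build_network(config, obs_dim, n_actions, init_rng)
        self.sync_target()
        self.optimizer = Adam(self.online.parameters(), lr=config.learning_rate)
        if config.prioritized:
            self.buffer: ReplayBuffer = PrioritizedBuffer(
                config.buffer_capacity, config.per_alpha, config.per_epsilon)
        else:
            self.buffer = ReplayBuffer(config.buffer_capacity)
        if config.categorical:
            self.atoms = np.linspace(config.v_min, config.v_max, config.n_atoms)
        self.train_steps_done = 0

    # ---- noise handling ----
    def resample_noise(self) -> None:
        for layer in self.online.noisy_layers():
            layer.resample_noise(self._noise_rng)
        for layer in self.target.noisy_layers():
            layer.resample_noise(self._noise_rng)

    def zero_noise(self) -> None:
        for net in (self.online, self.target):
            for layer in net.noisy_layers():
                layer.zero_noise()

    def sync_target(self) -> None:
        for src, dst in zip(self.online.parameters(), self.target.parameters()):
            dst.data[...] = src.data

    # ---- acting ----
    def q_values(self, obs: np.ndarray) -> np.ndarray:
        return self.online.q_values(np.atleast_2d(obs))[0]

    def act(self, obs: np.ndarray, eps: float = 0.0) -> int:
        if self.config.noisy and eps < 1.0:
            for layer in self.online.noisy_layers():
                layer.resample_noise(self._noise_rng)
        return select_action(self.q_values(obs), eps, self._explore_rng)

    def act_greedy(self, obs: np.ndarray) -> int:
        """Deterministic evaluation policy: noise off, argmax Q."""
        self.zero_noise()
        return select_action(self.q_values(obs), 0.0, self._explore_rng)

    # ---- learning ----
    def _beta(self) -> float:
        c = self.config
        frac = min(1.0, self.train_steps_done / max(1, c.training_steps))
        return c.per_beta0 + frac * (c.per_beta_final - c.per_beta0)

    def train_step(self) -> float:
        """One gradient update on the variant's loss; returns the loss."""
        c = self.config
        if len(self.buffer) < c.batch_size:
            raise RuntimeError("buffer not warm enough for a training batch")
        if c.prioritized:
            batch, idx, weights = self.buffer.sample(c.batch_size, self._buffer_rng,
                                                     self._beta())
        else:
            batch, idx, weights = self.buffer.sample(c.batch_size, self._buffer_rng)

        obs = np.stack([t.observation for t in batch])
        actions = np.array([t.action for t in batch])
        rewards = np.array([t.reward for t in batch])
        next_obs = np.stack([t.next_observation for t in batch])
        dones = np.array([t.done for t in batch])
        discounts = np.array([t.discount for t in batch])
        rows = np.arange(len(batch))

        self.resample_noise()  # one noise sample per training batch

        if c.categorical:
            next_dist_target = self.target.distributions(next_obs)
            if c.double:
                next_q = self.online.q_values(next_obs)
            else:
                next_q = next_dist_target @ self.atoms
            next_actions = np.argmax(next_q, axis=1)
            chosen_next = next_dist_target[rows, next_actions]
            m = categorical_project(rewards, dones, chosen_next, discounts, self.atoms)

            probs = self.online.distributions(obs)
            p_a = probs[rows, actions]
            ce = -np.sum(m * np.log(np.clip(p_a, 1e-12, None)), axis=1)
            loss = float(np.mean(weights * ce))
            grad_logits = np.zeros_like(probs)
            grad_logits[rows, actions] = (weights[:, None] * (p_a - m)) / len(batch)
            self.optimizer.zero_grad()
            self.online.backward_from_logits(grad_logits)
            priorities = ce
        else:
            q_next_target = self.target.q_values(next_obs)
            if c.double:
                q_next_online = self.online.q_values(next_obs)
                y = td_target_ddqn(rewards, dones, q_next_online, q_next_target,
                                   discounts)
            else:
                y = td_target_dqn(rewards, dones, q_next_target, discounts)
            q = self.online.q_values(obs)
            delta = q[rows, actions] - y
            loss = float(np.mean(weights * delta ** 2))
            grad_q = np.zeros_like(q)
            grad_q[rows, actions] = 2.0 * weights * delta / len(batch)
            self.optimizer.zero_grad()
            self.online.backward_from_q(grad_q)
            priorities = np.abs(delta)

        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at training step {self.train_steps_done}")
        self.optimizer.step()
        self.buffer.update_priorities(idx, priorities)
        self.train_steps_done += 1
        if self.train_steps_done % c.target_update_period == 0:
            self.sync_target()
        return loss

    # ---- persistence ----
    def save(self, path) -> None:
        """Checkpoint: weights in one .npz, config + seed in a JSON sidecar."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.online.parameters())}
        np.savez(path, **arrays)
        meta = {"config": asdict(self.config), "seed": self.seed,
                "obs_dim": self.obs_dim, "n_actions": self.n_actions,
                "train_steps_done": self.train_steps_done}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "DQNAgent":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        agent = cls(meta["obs_dim"], meta["n_actions"],
                    AgentConfig(**meta["config"]), meta["seed"])
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            for i, p in enumerate(agent.online.parameters()):
                p.data[...] = data[f"p{i}"]
        agent.sync_target()
        agent.train_steps_done = meta["train_steps_done"]
        return agent


# ---------------------------------------------------------------------------
# training loop

def _scenario_stream(meal_seed: int):
    from glucorl.meals import generate_scenario
    i = 0
    while True:
        yield generate_scenario(meal_seed + i)
        i += 1


def train(env, config: AgentConfig, seed: int, meal_seed: int | None = None,
          log_path=None):
    """Train one agent for ``config.training_steps`` environment steps.

    Every episode draws the next scenario from a seeded training meal
    stream (sub-seeds ``meal_seed + episode``), so identical (seed,
    meal_seed, config) reproduce the exact same run. Returns the agent and
    a per-step log (step, episode, episodic_return, epsilon, loss).
    """
    if meal_seed is None:
        meal_seed = seed + 1_000_000
    agent = DQNAgent(env.obs_dim, env.n_actions, config, seed)
    scenarios = _scenario_stream(meal_seed)

    log: list[dict] = []
    episode = 0
    obs, _ = env.reset(next(scenarios))
    features = env.normalize(obs)
    ep_return = 0.0
    nstep_queue: list[tuple] = []
    n = config.multi_step
    gamma = config.discount

    for t in range(1, config.training_steps + 1):
        eps = epsilon(t - 1, config.eps0, config.eps_final, config.eps_decay)
        action = agent.act(features, eps)
        next_obs, r, terminated, truncated, _ = env.step(action)
        done = terminated or truncated
        next_features = env.normalize(next_obs)
        ep_return += r

        nstep_queue.append((features, action, r, next_features, done))
        if len(nstep_queue) >= n or done:
            while nstep_queue and (len(nstep_queue) >= n or done):
                ret, disc = 0.0, 1.0
                for (_, _, r_k, _, _) in nstep_queue[:n]:
                    ret += disc * r_k
                    disc *= gamma
                f0, a0, _, _, _ = nstep_queue[0]
                f_last, d_last = nstep_queue[min(n, len(nstep_queue)) - 1][3:5]
                agent.buffer.push(Transition(f0, a0, ret, f_last, d_last, disc))
                nstep_queue.pop(0)
                if not done:
                    break

        loss = np.nan
        if len(agent.buffer) >= max(config.learning_starts, config.batch_size):
            loss = agent.train_step()

        log.append({"step": t, "episode": episode, "epsilon": eps,
                    "loss": loss, "reward": r})
        if done:
            log[-1]["episodic_return"] = ep_return
            episode += 1
            ep_return = 0.0
            nstep_queue.clear()
            obs, _ = env.reset(next(scenarios))
            features = env.normalize(obs)
        else:
            features = next_features

    if log_path is not None:
        import csv
        with open(log_path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["step", "episode", "epsilon",
                                               "loss", "reward", "episodic_return"])
            w.writeheader()
            w.writerows(log)
    return agent, log
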