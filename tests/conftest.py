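import numpy as np
import pytest

from glucorl.env import GlucoseEnv
from glucorl.patient import PatientParameters, default_patient, find_steady_state


@pytest.fixture(scope="session")
def params() -> PatientParameters:
    return default_patient()


@pytest.fixture(scope="session")
def steady(params):
    """(steady state, b*) of the packaged patient at the 108 mg/dL target."""
    return find_steady_state(params, 108.0)


@pytest.fixture(scope="session")
def env(params) -> GlucoseEnv:
    """A1 environment around the packaged patient (frozen ICR)."""
    return GlucoseEnv(params, action_space_name="A1")


class ToyTargetEnv:
    """5-state chain MDP for policy-recovery oracles.

    Action 0 moves left, action 1 moves right (saturating at the ends);
    landing on the middle state (index 2) pays reward 1, everything else 0.
    Observations are one-hot; episodes last 20 steps. The unique optimal
    policy moves toward the middle from every non-middle state.
    """

    n_states = 5
    n_actions = 2
    obs_dim = 5
    horizon = 20

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)
        self.s = 0
        self.t = 0

    def _obs(self) -> np.ndarray:
        v = np.zeros(self.n_states)
        v[self.s] = 1.0
        return v

    def reset(self, scenario=None, seed=None):
        self.s = int(self.rng.integers(self.n_states))
        self.t = 0
        return self._obs(), {}

    def step(self, action: int):
        self.s = max(0, self.s - 1) if action == 0 else min(self.n_states - 1, self.s + 1)
        self.t += 1
        reward = 1.0 if self.s == 2 else 0.0
        return self._obs(), reward, self.t >= self.horizon, False, {}

    def normalize(self, obs):
        return obs

    @classmethod
    def optimal_q(cls, discount: float = 0.9) -> np.ndarray:
        """Brute-force value iteration on the known transition table."""
        nxt = np.zeros((cls.n_states, cls.n_actions), dtype=int)
        for s in range(cls.n_states):
            nxt[s, 0] = max(0, s - 1)
            nxt[s, 1] = min(cls.n_states - 1, s + 1)
        rew = (nxt == 2).astype(float)
        q = np.zeros((cls.n_states, cls.n_actions))
        for _ in range(1000):
            q = rew + discount * q.max(axis=1)[nxt]
        return q


@pytest.fixture
def toy_env_cls():
    return ToyTargetEnv
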