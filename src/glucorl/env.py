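"""Gym-style episodic environment for closed-loop basal insulin control.

The agent observes the last 30 min of 1-min BG samples plus its 4 most
recent basal actions, and picks one of a small set of basal rates every
30 min; the rate is held constant for the whole interval. Meal carbs enter
the gut as 1-min impulses at their scheduled minute, and — this being a
hybrid closed loop — the environment itself delivers a meal bolus computed
from the announced (estimated) carbs, unless the scenario flags the bolus
as skipped. Episodes last 36 h = 72 agent steps.

Reward: a Gaussian bump exp(-0.5 (g - 108)^2 / 900) of the BG at the
decision instant while the whole 30-min window stayed inside [70, 180]
mg/dL; any sample outside the bounds turns the step's reward into the
punishment -1000. Episodes never terminate early on a bounds breach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from glucorl.meals import EPISODE_MINUTES, MealScenario
from glucorl.patient import (
    PatientParameters,
    PatientState,
    find_steady_state,
    integrate_minute,
    measure_bg,
)

__all__ = [
    "BG_LOW",
    "BG_HIGH",
    "BG_REFERENCE",
    "PUNISHMENT",
    "STEP_MINUTES",
    "STEPS_PER_EPISODE",
    "Observation",
    "reward",
    "compute_bolus",
    "normalize_observation",
    "denormalize_observation",
    "action_space",
    "calibrate_icr",
    "GlucoseEnv",
]

BG_LOW = 70.0        # mg/dL, lower bound of normoglycemia
BG_HIGH = 180.0      # mg/dL, upper bound of normoglycemia
BG_REFERENCE = 108.0 # mg/dL, BG reference of the reward function
PUNISHMENT = -1000.0 # reward when BG leaves the valid bounds
REWARD_WIDTH_SQ = 900.0  # variance-like width of the Gaussian reward (mg/dL)^2

STEP_MINUTES = 30
STEPS_PER_EPISODE = EPISODE_MINUTES // STEP_MINUTES  # 72
BG_WINDOW = 30
INSULIN_WINDOW = 4


@dataclass(frozen=True)
class Observation:
    """Agent state: 30 recent 1-min BG samples + 4 last basal actions."""

    bg_window: tuple[float, ...]       # mg/dL, most recent last
    insulin_window: tuple[float, ...]  # mU/min, most recent last

    def __post_init__(self) -> None:
        if len(self.bg_window) != BG_WINDOW:
            raise ValueError(f"bg_window must hold {BG_WINDOW} samples")
        if len(self.insulin_window) != INSULIN_WINDOW:
            raise ValueError(f"insulin_window must hold {INSULIN_WINDOW} actions")


def reward(bg: float, bounds: tuple[float, float] = (BG_LOW, BG_HIGH),
           reference: float = BG_REFERENCE) -> float:
    """Gaussian reward inside the valid bounds, fixed punishment outside."""
    lo, hi = bounds
    if lo <= bg <= hi:
        return math.exp(-0.5 * (bg - reference) ** 2 / REWARD_WIDTH_SQ)
    return PUNISHMENT


def compute_bolus(estimated_carbs: float, icr: float, skipped: bool = False) -> float:
    """Meal bolus in U of insulin from announced carbs and the
    insulin-to-carb ratio (g/U). Skipped boluses deliver 0 U."""
    if estimated_carbs < 0:
        raise ValueError("estimated carbs must be non-negative")
    if icr <= 0:
        raise ValueError("insulin-to-carb ratio must be positive")
    return 0.0 if skipped else estimated_carbs / icr


def normalize_observation(obs: Observation, basal_rate: float) -> np.ndarray:
    """Flatten to a 34-vector: BG scaled by 1/100, insulin by 1/b*."""
    return np.concatenate([
        np.asarray(obs.bg_window, dtype=float) / 100.0,
        np.asarray(obs.insulin_window, dtype=float) / basal_rate,
    ])


def denormalize_observation(features: np.ndarray, basal_rate: float) -> Observation:
    """Inverse of :func:`normalize_observation`."""
    features = np.asarray(features, dtype=float)
    if features.shape != (BG_WINDOW + INSULIN_WINDOW,):
        raise ValueError("expected a 34-component feature vector")
    return Observation(
        bg_window=tuple(features[:BG_WINDOW] * 100.0),
        insulin_window=tuple(features[BG_WINDOW:] * basal_rate),
    )


def action_space(basal_rate: float, name: str = "A1") -> tuple[float, ...]:
    """Discrete basal-rate menus around the optimal basal b*.

    ``A1`` = {0, b*, 3b*}; ``A2`` = {0, b*/2, b*, 2b*, 3b*}. Both share the
    same minimum (pump stop) and maximum (3b*).
    """
    if name == "A1":
        return (0.0, basal_rate, 3.0 * basal_rate)
    if name == "A2":
        return (0.0, 0.5 * basal_rate, basal_rate, 2.0 * basal_rate, 3.0 * basal_rate)
    raise ValueError("action space must be 'A1' or 'A2'")


def calibrate_icr(
    params: PatientParameters,
    target_bg: float = BG_REFERENCE,
    meal_carbs: float = 60.0,
    horizon_min: int = 480,
    mode: str = "robust",
    bracket: tuple[float, float] = (5.0, 80.0),
    iterations: int = 40,
) -> float:
    """Patient-specific insulin-to-carb ratio by bisection.

    Finds the smallest ICR (largest bolus, hence smallest post-meal
    excursion) such that a nominal ``meal_carbs`` g meal bolused at mealtime
    on top of the basal b* causes no hypoglycemia (BG >= 70 mg/dL) over the
    following ``horizon_min`` minutes.

    ``mode='robust'`` (default) sizes the calibration bolus from the
    worst-case +30% overestimated carb count — the largest bolus the
    carb-counting error model can actually deliver for this meal — so the
    operational bolus can never cause hypoglycemia from the calibration
    meal. ``mode='nominal'`` uses the perfectly counted amount.
    """
    if mode not in ("robust", "nominal"):
        raise ValueError("mode must be 'robust' or 'nominal'")
    overestimate = 1.3 if mode == "robust" else 1.0
    steady, bstar = find_steady_state(params, target_bg)

    def nadir(icr: float) -> float:
        bolus_mu = compute_bolus(meal_carbs * overestimate, icr) * 1000.0
        state, worst = steady, math.inf
        for minute in range(horizon_min):
            u = bstar + (bolus_mu if minute == 0 else 0.0)
            state = integrate_minute(state, params, u, meal_carbs if minute == 0 else 0.0)
            worst = min(worst, measure_bg(state, params))
        return worst

    lo, hi = bracket
    if nadir(hi) < BG_LOW:
        raise RuntimeError("even the weakest bolus in the bracket causes hypoglycemia")
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if nadir(mid) >= BG_LOW:
            hi = mid
        else:
            lo = mid
    return hi


class EpisodeFinishedError(RuntimeError):
    """Raised when ``step`` is called on a finished episode."""


class GlucoseEnv:
    """Episodic glucose-control environment around one virtual patient.

    Follows the familiar 5-tuple step API:
    ``reset(scenario, seed) -> (obs, info)`` and
    ``step(action_index) -> (obs, reward, terminated, truncated, info)``.
    ``info`` carries the minute-wise BG trace of the step, meals delivered,
    and boluses given.
    """

    def __init__(
        self,
        params: PatientParameters,
        action_space_name: str = "A1",
        target_bg: float = BG_REFERENCE,
        icr: float | None = None,
    ):
        self.params = params
        self.target_bg = target_bg
        self.steady_state, self.basal_rate = find_steady_state(params, target_bg)
        self.actions = action_space(self.basal_rate, action_space_name)
        self.action_space_name = action_space_name
        if icr is None:
            icr = params.icr_g_per_u
        if icr is None:
            icr = calibrate_icr(params, target_bg)
        self.icr = float(icr)
        self._scenario: MealScenario | None = None
        self._state: PatientState | None = None
        self._step_count = 0
        self._done = True

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def obs_dim(self) -> int:
        return BG_WINDOW + INSULIN_WINDOW

    def reset(self, scenario: MealScenario, seed: int | None = None):
        """Start an episode: patient at the b* steady state, windows filled
        with the steady BG and b*. The environment itself is deterministic;
        ``seed`` is accepted for API compatibility and ignored."""
        self._scenario = scenario
        self._state = self.steady_state
        self._step_count = 0
        self._done = False
        steady_bg = measure_bg(self.steady_state, self.params)
        self._bg_window = [steady_bg] * BG_WINDOW
        self._insulin_window = [self.basal_rate] * INSULIN_WINDOW
        obs = Observation(tuple(self._bg_window), tuple(self._insulin_window))
        return obs, {"bg": steady_bg}

    def step(self, action_index: int):
        """Hold the selected basal rate for 30 simulated minutes."""
        if self._done or self._scenario is None:
            raise EpisodeFinishedError("call reset() before stepping")
        if not 0 <= action_index < len(self.actions):
            raise IndexError(f"action index {action_index} out of range")
        basal = self.actions[action_index]
        t0 = self._step_count * STEP_MINUTES
        # meals whose (floored) minute falls inside this 30-min window
        window_meals = [
            m for m in self._scenario.meals if t0 <= int(m.time) < t0 + STEP_MINUTES
        ]
        meal_by_minute = {int(m.time): m for m in window_meals}
        bgs, boluses = [], []
        state = self._state
        for k in range(STEP_MINUTES):
            minute = t0 + k
            carbs, extra_insulin = 0.0, 0.0
            meal = meal_by_minute.get(minute)
            if meal is not None:
                carbs = meal.actual_carbs
                bolus_u = compute_bolus(meal.estimated_carbs, self.icr, meal.bolus_skipped)
                if bolus_u > 0:
                    extra_insulin = bolus_u * 1000.0  # U -> mU over one minute
                    boluses.append((minute, bolus_u))
            state = integrate_minute(state, self.params, basal + extra_insulin, carbs)
            bgs.append(measure_bg(state, self.params))
        self._state = state
        self._bg_window = bgs
        self._insulin_window = self._insulin_window[1:] + [basal]
        self._step_count += 1
        terminated = self._step_count >= STEPS_PER_EPISODE
        self._done = terminated

        in_bounds = all(BG_LOW <= g <= BG_HIGH for g in bgs)
        r = reward(bgs[-1]) if in_bounds else PUNISHMENT
        obs = Observation(tuple(self._bg_window), tuple(self._insulin_window))
        info = {
            "bg_trace": list(bgs),
            "meals": [(int(m.time), m.actual_carbs) for m in window_meals],
            "boluses": boluses,
            "basal": basal,
        }
        return obs, r, terminated, False, info

    def normalize(self, obs: Observation) -> np.ndarray:
        return normalize_observation(obs, self.basal_rate)
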