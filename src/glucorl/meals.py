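"""Seeded daily meal-scenario generation.

Each simulated day carries four meals at fixed clock times with uniform
amount noise, timing jitter, and a multiplicative carbohydrate-counting
error that corrupts the announced (estimated) carbs used for boluses:

====================  ==========  ============
meal                  base (g)    clock time
====================  ==========  ============
breakfast             40          08:00 +/- 30 min
lunch                 80          12:00 +/- 30 min
dinner                60          18:00 +/- 30 min
supper                30          22:00 +/- 30 min
====================  ==========  ============

Amounts receive U(-20, 20) g of noise (clipped at zero); estimated carbs are
actual * (1 + U(-0.3, 0.3)). Episodes last 36 h (2160 min) starting at
midnight, so the night after supper and the early hours of day 2 are
meal-free. Generation is a pure function of (seed, config).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MealEvent",
    "MealScenario",
    "MealConfig",
    "DEFAULT_MEAL_CONFIG",
    "EPISODE_MINUTES",
    "generate_scenario",
    "generate_test_set",
    "apply_bolus_skipping",
    "scenarios_to_csv",
    "scenarios_from_csv",
]

#: Episode length: 1.5 days = 36 h.
EPISODE_MINUTES = 2160


@dataclass(frozen=True)
class MealEvent:
    """One meal: when it happens, what was eaten, what was announced."""

    time: float              # minutes since episode start (midnight)
    actual_carbs: float      # g of CHO actually ingested
    estimated_carbs: float   # g of CHO announced for bolus calculation
    bolus_skipped: bool = False

    def __post_init__(self) -> None:
        if self.actual_carbs < 0 or self.estimated_carbs < 0:
            raise ValueError("carb amounts must be non-negative")


@dataclass(frozen=True)
class MealScenario:
    """An ordered day of meals plus the seed that produced it."""

    meals: tuple[MealEvent, ...]
    seed: int
    episode_length: int = EPISODE_MINUTES

    def __post_init__(self) -> None:
        times = [m.time for m in self.meals]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("meal times must be strictly increasing")
        if times and not (0 <= times[0] and times[-1] < self.episode_length):
            raise ValueError("meal times must lie within the episode")


@dataclass(frozen=True)
class MealConfig:
    """Base meal schedule and noise magnitudes."""

    base_times: tuple[float, ...] = (480.0, 720.0, 1080.0, 1320.0)
    base_amounts: tuple[float, ...] = (40.0, 80.0, 60.0, 30.0)
    amount_noise: float = 20.0       # +/- g, uniform
    time_jitter: float = 30.0        # +/- min, uniform
    counting_error: float = 0.3      # +/- fraction, uniform, multiplicative

    def __post_init__(self) -> None:
        if len(self.base_times) != len(self.base_amounts):
            raise ValueError("base_times and base_amounts lengths differ")
        if any(a < 0 for a in self.base_amounts):
            raise ValueError("base amounts must be non-negative")


DEFAULT_MEAL_CONFIG = MealConfig()


def generate_scenario(rng_seed: int, config: MealConfig = DEFAULT_MEAL_CONFIG) -> MealScenario:
    """Draw one day of meals.

    Per meal, in order: amount noise, timing jitter, counting error — three
    uniform draws from a ``numpy`` generator seeded with ``rng_seed``, so the
    scenario is a pure function of (seed, config).
    """
    rng = np.random.default_rng(rng_seed)
    meals = []
    for t0, a0 in zip(config.base_times, config.base_amounts):
        actual = max(0.0, a0 + rng.uniform(-config.amount_noise, config.amount_noise))
        time = t0 + rng.uniform(-config.time_jitter, config.time_jitter)
        estimated = actual * (1.0 + rng.uniform(-config.counting_error, config.counting_error))
        meals.append(MealEvent(time=time, actual_carbs=actual, estimated_carbs=estimated))
    meals.sort(key=lambda m: m.time)
    return MealScenario(meals=tuple(meals), seed=rng_seed)


def generate_test_set(
    seed: int,
    n_episodes: int = 100,
    config: MealConfig = DEFAULT_MEAL_CONFIG,
) -> list[MealScenario]:
    """The fixed evaluation set: ``n_episodes`` scenarios from consecutive
    sub-seeds ``seed + i``. Using a master seed distinct from the training
    stream keeps the two disjoint by construction."""
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    return [generate_scenario(seed + i, config) for i in range(n_episodes)]


def apply_bolus_skipping(
    scenario: MealScenario, skip_probability: float, rng_seed: int
) -> MealScenario:
    """Independently flag each meal's bolus as skipped with the given
    probability; amounts and times are untouched."""
    if not 0.0 <= skip_probability <= 1.0:
        raise ValueError("skip_probability must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    meals = tuple(
        replace(m, bolus_skipped=bool(rng.uniform() < skip_probability))
        for m in scenario.meals
    )
    return replace(scenario, meals=meals)


def scenarios_to_csv(scenarios: list[MealScenario], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["episode", "meal_index", "time_min", "actual_g", "estimated_g", "skipped"])
        for ep, sc in enumerate(scenarios):
            for i, m in enumerate(sc.meals):
                w.writerow([ep, i, repr(m.time), repr(m.actual_carbs),
                            repr(m.estimated_carbs), int(m.bolus_skipped)])


def scenarios_from_csv(path) -> list[MealScenario]:
    rows: dict[int, list[MealEvent]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(int(rec["episode"]), []).append(
                MealEvent(
                    time=float(rec["time_min"]),
                    actual_carbs=float(rec["actual_g"]),
                    estimated_carbs=float(rec["estimated_g"]),
                    bolus_skipped=bool(int(rec["skipped"])),
                )
            )
    return [
        MealScenario(meals=tuple(rows[ep]), seed=-1)
        for ep in sorted(rows)
    ]
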