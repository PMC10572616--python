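"""Evaluation protocol: greedy rollouts on the fixed test set and
time-in-range metrics.

TIR/TAR/TBR are computed on the minute-wise mean BG trace across the 100
test episodes (the primary reading), with per-episode variants reported
alongside; the bounds 70 and 180 mg/dL count as in range. mu and sigma are
the per-episode BG mean and SD averaged over episodes, and sigma_A is the
per-episode population SD of the 72 basal actions, likewise averaged.
A useful identity when reading TIR: 1 percentage point = 14.4 min per
24 h-equivalent day.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict

import numpy as np

from glucorl.env import BG_LOW, BG_HIGH, GlucoseEnv, STEPS_PER_EPISODE
from glucorl.meals import EPISODE_MINUTES, MealScenario, apply_bolus_skipping

__all__ = [
    "EpisodeTrace",
    "MetricsReport",
    "mean_trace",
    "time_in_ranges",
    "episode_statistics",
    "run_baseline",
    "run_policy",
    "evaluate_agent",
    "metrics_to_csv",
    "plot_mean_trace",
]


@dataclass(frozen=True)
class EpisodeTrace:
    """Minute-wise BG plus the per-step control record of one episode."""

    bg_per_minute: np.ndarray     # 2160 values, mg/dL
    actions_per_step: np.ndarray  # 72 basal rates, mU/min
    rewards_per_step: np.ndarray  # 72 scalars
    boluses: tuple[tuple[int, float], ...] = ()  # (minute, U)

    def __post_init__(self) -> None:
        if len(self.bg_per_minute) != EPISODE_MINUTES:
            raise ValueError(f"expected {EPISODE_MINUTES} BG samples")
        if len(self.actions_per_step) != STEPS_PER_EPISODE:
            raise ValueError(f"expected {STEPS_PER_EPISODE} actions")
        if len(self.rewards_per_step) != STEPS_PER_EPISODE:
            raise ValueError(f"expected {STEPS_PER_EPISODE} rewards")


@dataclass(frozen=True)
class MetricsReport:
    """TIR/TAR/TBR on the mean trace plus episode-averaged statistics."""

    tir: float        # % of minutes of the mean trace in [70, 180]
    tar: float        # % above 180
    tbr: float        # % below 70
    mean_bg: float    # mg/dL, per-episode mean averaged over episodes
    sd_bg: float      # mg/dL, per-episode SD averaged over episodes
    sd_action: float  # mU/min, per-episode SD of actions averaged over episodes
    tir_per_episode: float = float("nan")  # episode-averaged TIR, secondary

    def __post_init__(self) -> None:
        if abs(self.tir + self.tar + self.tbr - 100.0) > 1e-9:
            raise ValueError("TIR + TAR + TBR must equal 100")


def mean_trace(traces: list[EpisodeTrace]) -> np.ndarray:
    """Element-wise mean BG across episodes at each minute."""
    if not traces:
        raise ValueError("need at least one trace")
    return np.mean([t.bg_per_minute for t in traces], axis=0)


def time_in_ranges(trace: np.ndarray, low: float = BG_LOW,
                   high: float = BG_HIGH) -> tuple[float, float, float]:
    """(TIR, TAR, TBR) percentages of a BG trace; bounds are inclusive."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    tir = 100.0 * np.mean((trace >= low) & (trace <= high))
    tar = 100.0 * np.mean(trace > high)
    tbr = 100.0 * np.mean(trace < low)
    return float(tir), float(tar), float(tbr)


def episode_statistics(traces: list[EpisodeTrace]) -> tuple[float, float, float]:
    """(mu, sigma, sigma_A): per-episode BG mean, BG SD, and action SD,
    each averaged (unweighted) across episodes. SDs use the population
    (N-denominator) convention."""
    if not traces:
        raise ValueError("need at least one trace")

    def pop_std(x: np.ndarray) -> float:
        # exact zero for constant sequences (np.std leaves ~1e-16 residue)
        return 0.0 if np.ptp(x) == 0 else float(np.std(x))

    mu = float(np.mean([t.bg_per_minute.mean() for t in traces]))
    sd = float(np.mean([pop_std(t.bg_per_minute) for t in traces]))
    sd_a = float(np.mean([pop_std(t.actions_per_step) for t in traces]))
    return mu, sd, sd_a


class _ConstantBasalPolicy:
    """The clinical baseline: always deliver the optimal basal b*."""

    def __init__(self, env: GlucoseEnv):
        self._index = env.actions.index(env.basal_rate)

    def act_greedy(self, features) -> int:
        return self._index


def run_policy(policy, env: GlucoseEnv, test_set: list[MealScenario],
               skip_probability: float = 0.0,
               skip_seed: int = 0) -> list[EpisodeTrace]:
    """Greedy rollout of a policy on every scenario of the test set.

    ``policy`` needs an ``act_greedy(features) -> action_index`` method.
    With ``skip_probability`` > 0 each scenario first has meal boluses
    independently skipped (sub-seed ``skip_seed + episode``).
    """
    traces = []
    for ep, scenario in enumerate(test_set):
        if skip_probability > 0.0:
            scenario = apply_bolus_skipping(scenario, skip_probability,
                                            skip_seed + ep)
        obs, _ = env.reset(scenario)
        features = env.normalize(obs)
        bgs, actions, rewards, boluses = [], [], [], []
        done = False
        while not done:
            a = policy.act_greedy(features)
            obs, r, terminated, truncated, info = env.step(a)
            features = env.normalize(obs)
            done = terminated or truncated
            bgs.extend(info["bg_trace"])
            actions.append(info["basal"])
            rewards.append(r)
            boluses.extend(info["boluses"])
        traces.append(EpisodeTrace(
            bg_per_minute=np.array(bgs),
            actions_per_step=np.array(actions),
            rewards_per_step=np.array(rewards),
            boluses=tuple(boluses),
        ))
    return traces


def run_baseline(test_set: list[MealScenario], env: GlucoseEnv,
                 skip_probability: float = 0.0,
                 skip_seed: int = 0) -> list[EpisodeTrace]:
    """Fixed-b* baseline with environment-managed meal boluses."""
    return run_policy(_ConstantBasalPolicy(env), env, test_set,
                      skip_probability, skip_seed)


def summarize(traces: list[EpisodeTrace]) -> MetricsReport:
    """Metrics of a set of episode traces."""
    mt = mean_trace(traces)
    tir, tar, tbr = time_in_ranges(mt)
    mu, sd, sd_a = episode_statistics(traces)
    tir_ep = float(np.mean([time_in_ranges(t.bg_per_minute)[0] for t in traces]))
    return MetricsReport(tir=tir, tar=tar, tbr=tbr, mean_bg=mu, sd_bg=sd,
                         sd_action=sd_a, tir_per_episode=tir_ep)


def evaluate_agent(agent, env: GlucoseEnv, test_set: list[MealScenario],
                   skip_probability: float = 0.0,
                   skip_seed: int = 0) -> tuple[MetricsReport, list[EpisodeTrace]]:
    """Greedy evaluation of a trained agent (or any act_greedy policy) on
    the fixed test set; the bolus-skipping experiment passes
    ``skip_probability=0.1``."""
    traces = run_policy(agent, env, test_set, skip_probability, skip_seed)
    return summarize(traces), traces


def write_episode_trace(trace: EpisodeTrace, scenario: MealScenario, path) -> None:
    """Minute-wise CSV of one episode: minute, bg_mgdl, basal_mU_min,
    bolus_U, carbs_g, reward (reward recorded at its decision minute)."""
    bolus_by_minute = dict(trace.boluses)
    carbs_by_minute = {int(m.time): m.actual_carbs for m in scenario.meals}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["minute", "bg_mgdl", "basal_mU_min", "bolus_U", "carbs_g",
                    "reward"])
        for minute, bg in enumerate(trace.bg_per_minute):
            step = minute // (EPISODE_MINUTES // STEPS_PER_EPISODE)
            is_decision = (minute + 1) % (EPISODE_MINUTES // STEPS_PER_EPISODE) == 0
            w.writerow([
                minute, repr(float(bg)),
                repr(float(trace.actions_per_step[step])),
                repr(float(bolus_by_minute.get(minute, 0.0))),
                repr(float(carbs_by_minute.get(minute, 0.0))),
                repr(float(trace.rewards_per_step[step])) if is_decision else "",
            ])


def metrics_to_csv(rows: dict[str, MetricsReport], path) -> None:
    """Write an algorithm -> metrics table (Tables 1-3 layout)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["algorithm", "tir", "tar", "tbr", "mean_bg", "sd_bg",
                    "sd_action", "tir_per_episode"])
        for name, rep in rows.items():
            d = asdict(rep)
            w.writerow([name] + [repr(d[k]) for k in
                                 ("tir", "tar", "tbr", "mean_bg", "sd_bg",
                                  "sd_action", "tir_per_episode")])


def plot_mean_trace(traces: list[EpisodeTrace], path, title: str = "") -> None:
    """Mean BG per minute with an SD confidence band and dotted 70/180
    normoglycemia bounds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.array([t.bg_per_minute for t in traces])
    mt, sd = arr.mean(axis=0), arr.std(axis=0)
    minutes = np.arange(arr.shape[1])
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(minutes, mt, color="crimson", lw=1.2, label="mean BG")
    ax.fill_between(minutes, mt - sd, mt + sd, color="crimson", alpha=0.25,
                    label="± SD")
    for bound in (BG_LOW, BG_HIGH):
        ax.axhline(bound, ls=":", color="tab:blue", lw=1)
    ax.set_xlabel("minute")
    ax.set_ylabel("BG (mg/dL)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
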