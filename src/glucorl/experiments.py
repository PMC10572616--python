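"""Reproducible drivers for the three benchmark experiments.

Experiment 1: 3-action space (A1), batch 128 — compare all controllers.
Experiment 2: 5-action space (A2), batch 512 — the only changed
hyperparameter is the batch size.
Experiment 3: experiment-1 agents evaluated with meal boluses skipped at
random with 10% probability; also reports the per-episode action SD.

Every run directory receives a JSON manifest (config, seeds, package
version) sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

import glucorl
from glucorl.agents import VARIANTS, AgentConfig, DQNAgent, train
from glucorl.env import GlucoseEnv
from glucorl.evaluation import (
    MetricsReport,
    evaluate_agent,
    metrics_to_csv,
    plot_mean_trace,
    run_baseline,
    summarize,
)
from glucorl.meals import generate_test_set
from glucorl.patient import PatientParameters, default_patient, load_patient

__all__ = ["ExperimentConfig", "run_experiment", "experiment_defaults"]

_EXPERIMENT_PRESETS = {
    1: {"action_space": "A1", "batch_size": 128, "skip_probability": 0.0},
    2: {"action_space": "A2", "batch_size": 512, "skip_probability": 0.0},
    3: {"action_space": "A1", "batch_size": 128, "skip_probability": 0.1},
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment run: which algorithms, which protocol, which seeds."""

    experiment_id: int = 1
    algorithms: tuple[str, ...] = ("baseline",)
    train_seed: int = 0
    test_seed: int = 20_000
    n_test_episodes: int = 100
    training_steps: int = 100_000
    output_dir: str = "results"
    patient_file: str | None = None  # None -> packaged 70 kg patient
    checkpoint_dir: str | None = None  # evaluate-only mode when set

    def __post_init__(self) -> None:
        if self.experiment_id not in _EXPERIMENT_PRESETS:
            raise ValueError("experiment_id must be 1, 2, or 3")
        for alg in self.algorithms:
            if alg != "baseline" and alg not in VARIANTS:
                raise ValueError(
                    f"unknown algorithm {alg!r}; choose 'baseline' or one of {VARIANTS}")

    @property
    def action_space(self) -> str:
        return _EXPERIMENT_PRESETS[self.experiment_id]["action_space"]

    @property
    def batch_size(self) -> int:
        return _EXPERIMENT_PRESETS[self.experiment_id]["batch_size"]

    @property
    def skip_probability(self) -> float:
        return _EXPERIMENT_PRESETS[self.experiment_id]["skip_probability"]


def experiment_defaults(experiment_id: int) -> dict:
    """Protocol constants (action space, batch size, skip probability)."""
    return dict(_EXPERIMENT_PRESETS[experiment_id])


def _config_hash(config: ExperimentConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def _load_params(config: ExperimentConfig) -> PatientParameters:
    if config.patient_file is None:
        return default_patient()
    return load_patient(config.patient_file)


def run_experiment(config: ExperimentConfig) -> dict[str, MetricsReport]:
    """Train (or load) each listed algorithm, evaluate on the fixed test
    set, and write the metrics table, plots, and a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = _load_params(config)
    env = GlucoseEnv(params, action_space_name=config.action_space)
    test_set = generate_test_set(config.test_seed, config.n_test_episodes)

    reports: dict[str, MetricsReport] = {}
    for alg in config.algorithms:
        if alg == "baseline":
            traces = run_baseline(test_set, env,
                                  skip_probability=config.skip_probability,
                                  skip_seed=config.test_seed + 50_000)
            reports[alg] = summarize(traces)
        else:
            agent = _obtain_agent(alg, config, env, out)
            reports[alg], traces = evaluate_agent(
                agent, env, test_set,
                skip_probability=config.skip_probability,
                skip_seed=config.test_seed + 50_000)
        plot_mean_trace(traces, out / f"exp{config.experiment_id}_{alg}.png",
                        title=f"experiment {config.experiment_id}: {alg}")

    metrics_to_csv(reports, out / f"exp{config.experiment_id}_metrics.csv")
    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "protocol": experiment_defaults(config.experiment_id),
        "package_version": glucorl.__version__,
        "patient": {k: getattr(params, k) for k in ("body_weight", "icr_g_per_u")},
        "basal_rate": env.basal_rate,
        "icr": env.icr,
    }
    (out / f"exp{config.experiment_id}_manifest.json").write_text(
        json.dumps(manifest, indent=2))
    return reports


def _obtain_agent(alg: str, config: ExperimentConfig, env: GlucoseEnv,
                  out: Path) -> DQNAgent:
    if config.checkpoint_dir is not None:
        ckpt = Path(config.checkpoint_dir) / f"{alg}.npz"
        if not ckpt.exists():
            raise FileNotFoundError(f"missing checkpoint {ckpt}")
        return DQNAgent.load(ckpt)
    agent_config = AgentConfig(variant=alg, batch_size=config.batch_size,
                               training_steps=config.training_steps)
    agent, _ = train(env, agent_config, seed=config.train_seed,
                     log_path=out / f"exp{config.experiment_id}_{alg}_train.csv")
    agent.save(out / f"{alg}.npz")
    return agent
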