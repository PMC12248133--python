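"""End-to-end experiment pipeline shared by the CLI and reproduction scripts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import SACAgent, evaluate_policy
from .config import ExperimentConfig
from .envs import GlucoseEnv, run_constant_basal
from .federation import FedClient, RoundConfig, ServerState, run_round
from .metrics import GlycemicReport, cohort_aggregate, glycemic_report, render_table
from .patient_sim import make_cohort, make_scenario
from .reward import bg_risk


def build_env(config: ExperimentConfig, patient, scenario_seed: int) -> GlucoseEnv:
    sc = config.scenario
    scenario = make_scenario(sc.days, sc.meals_per_day, scenario_seed,
                             carb_range=tuple(sc.carb_ranges[patient.cohort]))
    return GlucoseEnv(
        patient, scenario, reward_config=config.reward_config(),
        days=sc.days, k_history=config.k_history,
        cgm_noise_sd=config.cgm_noise_sd, cgm_lag_min=config.cgm_lag_min)


def build_patients(config: ExperimentConfig) -> dict[str, list]:
    """Training patients per cohort (held-out patients use a disjoint seed)."""
    return {c: make_cohort(c, n, config.seed_for(f"cohort/{c}"))
            for c, n in config.cohort_sizes.items() if n > 0}


def build_heldout_patients(config: ExperimentConfig) -> dict[str, list]:
    return {c: make_cohort(c, config.n_heldout_patients,
                           config.seed_for(f"heldout/{c}"))
            for c, n in config.cohort_sizes.items() if n > 0}


def build_clients(config: ExperimentConfig) -> list[FedClient]:
    clients = []
    for cohort, patients in build_patients(config).items():
        for i, patient in enumerate(patients):
            env = build_env(config, patient, config.seed_for(f"scenario/{cohort}", i))
            val_env = build_env(config, patient,
                                config.seed_for(f"val-scenario/{cohort}", i))
            agent = SACAgent(
                config.agent_config(action_scale=env.max_rate),
                seed=config.seed_for(f"agent/{cohort}", i))
            clients.append(FedClient(patient.patient_id, agent, env, val_env))
    return clients


@dataclass
class TrainResult:
    server: ServerState
    clients: list[FedClient]
    round_logs: list[dict] = field(default_factory=list)

    def round_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{k: v for k, v in row.items() if k != "final_epoch_log"}
                             for row in self.round_logs])


def train_federated(config: ExperimentConfig,
                    clients: list[FedClient] | None = None) -> TrainResult:
    """Run the configured number of synchronous federated rounds."""
    clients = clients if clients is not None else build_clients(config)
    fed = config.federation
    server = ServerState()
    rc = RoundConfig(local_epochs=fed.local_epochs,
                     steps_per_epoch=fed.steps_per_epoch,
                     updates_per_epoch=fed.updates_per_epoch,
                     strategy=fed.strategy, lambda_risk=fed.lambda_risk,
                     eval_seed=config.seed_for("round-eval"),
                     early_stopping_patience=fed.early_stopping_patience)
    logs: list[dict] = []
    for _ in range(fed.rounds):
        server, rows = run_round(clients, server, rc)
        logs.extend(rows)
    return TrainResult(server=server, clients=clients, round_logs=logs)


@dataclass
class EvalResult:
    reports: list[GlycemicReport]
    labels: list[str]
    baseline_reports: list[GlycemicReport]
    traces: dict[str, object]
    summary: dict[str, GlycemicReport] = field(init=False)
    baseline_summary: dict[str, GlycemicReport] = field(init=False)

    def __post_init__(self):
        self.summary = cohort_aggregate(self.reports, self.labels)
        self.baseline_summary = cohort_aggregate(self.baseline_reports, self.labels)

    def table(self) -> dict:
        return render_table(self.summary)


def evaluate_global(config: ExperimentConfig, result: TrainResult,
                    use_cgm: bool = False) -> EvalResult:
    """Deterministic rollout of the global policy on held-out patients and
    held-out meal scenarios, with a constant-basal baseline on the same
    scenarios for paired comparison."""
    reports, labels, baselines, traces = [], [], [], {}
    for cohort, patients in build_heldout_patients(config).items():
        for i, patient in enumerate(patients):
            env = build_env(config, patient, config.seed_for(f"eval-scenario/{cohort}", i))
            # Re-point the shared global policy at this patient's pump limit.
            eval_agent = SACAgent(config.agent_config(action_scale=env.max_rate),
                                  seed=config.seed_for("eval-agent"))
            eval_agent.set_params(result.server.global_params)
            ep_seed = config.seed_for(f"eval-episode/{cohort}", i)
            trace, _ = evaluate_policy(eval_agent, env, seed=ep_seed)
            reports.append(glycemic_report(trace, use_cgm=use_cgm))
            labels.append(cohort)
            traces[patient.patient_id] = trace
            baseline_env = build_env(config, patient,
                                     config.seed_for(f"eval-scenario/{cohort}", i))
            btrace = run_constant_basal(baseline_env, seed=ep_seed)
            baselines.append(glycemic_report(btrace, use_cgm=use_cgm))
            traces[patient.patient_id + "/baseline"] = btrace
    return EvalResult(reports=reports, labels=labels,
                      baseline_reports=baselines, traces=traces)


def validation_risk_by_round(result: TrainResult) -> list[float]:
    """Round-end validation mean risk of the broadcast global policy."""
    return [row["val_mean_risk"] for row in result.round_logs
            if row.get("client") == "_global"]
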