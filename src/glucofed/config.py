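"""Experiment configuration: cohorts, scenarios, reward, agent, federation schedules."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .agent import AgentConfig
from .exceptions import ConfigError
from .federation import STRATEGIES
from .reward import RewardConfig, validate_config

#: Per-cohort meal-size ranges (grams); children eat smaller meals.
DEFAULT_CARB_RANGES = {
    "child": (20.0, 40.0),
    "adolescent": (35.0, 60.0),
    "adult": (40.0, 70.0),
}


@dataclass
class ScenarioSpec:
    days: int = 5
    meals_per_day: int = 3
    carb_ranges: dict = field(default_factory=lambda: dict(DEFAULT_CARB_RANGES))


@dataclass
class FederationSpec:
    rounds: int = 10
    strategy: str = "risk_adjusted"
    lambda_risk: float = 0.5
    local_epochs: int = 1
    steps_per_epoch: int = 1440
    updates_per_epoch: int = 50
    early_stopping_patience: int | None = None


@dataclass
class ExperimentConfig:
    cohort_sizes: dict = field(default_factory=lambda: {
        "child": 10, "adolescent": 10, "adult": 10})
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    reward: dict = field(default_factory=dict)
    agent: dict = field(default_factory=dict)
    federation: FederationSpec = field(default_factory=FederationSpec)
    k_history: int = 12
    cgm_noise_sd: float = 5.0
    cgm_lag_min: float = 10.0
    n_heldout_patients: int = 1     # extra held-out patients per cohort
    master_seed: int = 1234
    outdir: str = "runs/default"

    def validate(self) -> "ExperimentConfig":
        for cohort, n in self.cohort_sizes.items():
            if cohort not in DEFAULT_CARB_RANGES:
                raise ConfigError(f"unknown cohort {cohort!r}")
            if n < 0:
                raise ConfigError("cohort sizes must be >= 0")
        if self.federation.strategy not in STRATEGIES:
            raise ConfigError(f"unknown federation strategy {self.federation.strategy!r}")
        validate_config(self.reward or None)
        self.agent_config()  # raises on invalid agent overrides
        return self

    def reward_config(self) -> RewardConfig:
        return validate_config(self.reward or None)

    def agent_config(self, **extra) -> AgentConfig:
        base = {"obs_dim": 3 * self.k_history + 2, **self.agent, **extra}
        known = {f.name for f in dataclasses.fields(AgentConfig)}
        unknown = set(base) - known
        if unknown:
            raise ConfigError(f"unknown agent config field(s): {sorted(unknown)}")
        return AgentConfig(**base).validate()

    # -- seeds --------------------------------------------------------------

    def seed_for(self, stream: str, k: int = 0) -> int:
        """Named, reproducible substream seed below 2**31."""
        digest = hashlib.sha256(f"{self.master_seed}:{stream}:{k}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["carb_ranges"] = {
            k: list(v) for k, v in d["scenario"]["carb_ranges"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "scenario" in d:
            sc = dict(d["scenario"])
            if "carb_ranges" in sc:
                sc["carb_ranges"] = {k: tuple(v) for k, v in sc["carb_ranges"].items()}
            d["scenario"] = ScenarioSpec(**sc)
        if "federation" in d:
            d["federation"] = FederationSpec(**d["federation"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def smoke_config(master_seed: int = 1234, cohorts: tuple[str, ...] = ("adult",),
                 n_per_cohort: int = 3) -> ExperimentConfig:
    """Reduced-scale preset: few patients, 1-day episodes, small recurrent nets.

    Sized so the full simulate -> train -> evaluate pipeline completes in
    minutes on one CPU while exercising every component at realistic (if
    abbreviated) settings.
    """
    return ExperimentConfig(
        cohort_sizes={c: (n_per_cohort if c in cohorts else 0)
                      for c in ("child", "adolescent", "adult")},
        scenario=ScenarioSpec(days=1, meals_per_day=3),
        agent={
            "gru_layers": 1, "hidden_units": 32, "fc_units": 32,
            "batch_size": 32, "sequence_length": 8, "burn_in": 2,
            "discount": 0.98, "actor_lr": 1e-3, "critic_lr": 1e-3,
            "temperature_lr": 1e-3, "polyak_factor": 0.02,
            "dropout_rate": 0.0, "min_buffer": 256,
            "replay_capacity": 20_000,
        },
        federation=FederationSpec(
            rounds=3, strategy="risk_adjusted", lambda_risk=0.5,
            local_epochs=4, steps_per_epoch=576, updates_per_epoch=250),
        master_seed=master_seed,
        outdir="runs/smoke",
    ).validate()


def full_config(master_seed: int = 1234) -> ExperimentConfig:
    """The full study protocol: 10 patients per cohort, 5-day episodes,
    300 training epochs split across federated rounds.  Hours of CPU."""
    return ExperimentConfig(
        cohort_sizes={"child": 10, "adolescent": 10, "adult": 10},
        scenario=ScenarioSpec(days=5, meals_per_day=3),
        agent={"epochs": 300},
        federation=FederationSpec(
            rounds=30, local_epochs=10, steps_per_epoch=1440,
            updates_per_epoch=50, early_stopping_patience=5),
        master_seed=master_seed,
        outdir="runs/full",
    ).validate()
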