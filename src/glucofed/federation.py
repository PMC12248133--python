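"""Synchronous federated loop: local training, update packaging, weighted averaging, broadcast.

Clients never transmit raw glucose/insulin series.  A ModelUpdate carries the
flattened policy parameters, the client's sample count for the round, and the
mean blood-glucose risk over its evaluation window; the server combines the
parameter vectors by federated averaging with uniform, sample-proportional,
or risk-adjusted weights.  Risk adjustment up-weights clients whose recent
evaluation showed higher glycemic risk so the global policy attends to the
difficult profiles:

    w_i  propto  n_i * (1 + lambda_risk * rtilde_i)

with rtilde_i the min-max normalization of mean risk within the round.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .agent import SACAgent, PolicyParams, evaluate_policy, train_local
from .exceptions import ConfigError, ValidationError
from .reward import RewardConfig, bg_risk

STRATEGIES = ("uniform", "by_samples", "risk_adjusted")


@dataclass(frozen=True)
class ModelUpdate:
    client_id: str
    params: PolicyParams
    num_samples: int
    mean_risk: float
    reward_config: RewardConfig | None = None

    def to_bytes(self) -> bytes:
        """Canonical serialization (what would cross the wire)."""
        payload = {
            "client_id": self.client_id,
            "num_samples": self.num_samples,
            "mean_risk": self.mean_risk,
            "reward_config": (self.reward_config.__dict__
                              if self.reward_config is not None else None),
            "params": self.params.vector.tolist(),
            "index": [[n, list(s), o] for n, s, o in self.params.index],
        }
        return json.dumps(payload).encode()


@dataclass(frozen=True)
class AggregationPlan:
    weights: np.ndarray  # >= 0, sums to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("plan weights must be >= 0 and sum to 1")


def package_update(agent: SACAgent, eval_trace, client_id: str,
                   num_samples: int | None = None,
                   reward_config: RewardConfig | None = None) -> ModelUpdate:
    """Flatten the agent's parameters into a privacy-safe update.

    ``mean_risk`` is computed from the evaluation trace *here* and only the
    scalar is retained; the trace itself never enters the update.
    """
    params = agent.get_params()
    if not np.all(np.isfinite(params.vector)):
        raise ValidationError(f"refusing to package non-finite parameters for {client_id}")
    glucose = np.asarray(getattr(eval_trace, "plasma_glucose", []), dtype=float)
    mean_risk = float(np.mean(bg_risk(glucose))) if glucose.size else 0.0
    n = agent.transitions_collected if num_samples is None else int(num_samples)
    return ModelUpdate(client_id=client_id, params=params, num_samples=n,
                       mean_risk=mean_risk, reward_config=reward_config)


def make_plan(updates: list[ModelUpdate], strategy: str = "risk_adjusted",
              lambda_risk: float = 0.5) -> AggregationPlan:
    """Per-client aggregation weights, normalized to sum to one."""
    if not updates:
        raise ValidationError("cannot build a plan from zero updates")
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if lambda_risk < 0:
        raise ConfigError("lambda_risk must be >= 0")
    m = len(updates)
    if strategy == "uniform":
        w = np.full(m, 1.0 / m)
        return AggregationPlan(w)
    n = np.array([u.num_samples for u in updates], dtype=float)
    if n.sum() == 0:
        n = np.ones(m)
    if strategy == "by_samples":
        w = n / n.sum()
        return AggregationPlan(w)
    risk = np.array([u.mean_risk for u in updates], dtype=float)
    span = risk.max() - risk.min()
    rtilde = (risk - risk.min()) / span if span > 0 else np.zeros(m)
    w = n * (1.0 + lambda_risk * rtilde)
    return AggregationPlan(w / w.sum())


def aggregate(updates: list[ModelUpdate], plan: AggregationPlan) -> PolicyParams:
    """Elementwise weighted average of the client parameter vectors."""
    if len(updates) != len(plan.weights):
        raise ValidationError("plan does not match the update list")
    ref = updates[0].params
    out = np.zeros_like(ref.vector)
    for u, w in zip(updates, plan.weights):
        if u.params.vector.shape != ref.vector.shape:
            raise ValidationError(
                f"parameter shape mismatch for client {u.client_id}")
        out += w * u.params.vector
    return PolicyParams(vector=out, index=ref.index)


@dataclass
class FedClient:
    client_id: str
    agent: SACAgent
    env: object
    val_env: object | None = None


@dataclass
class ServerState:
    global_params: PolicyParams | None = None
    round: int = 0


@dataclass
class RoundConfig:
    local_epochs: int = 1
    steps_per_epoch: int = 288
    updates_per_epoch: int | None = None
    strategy: str = "risk_adjusted"
    lambda_risk: float = 0.5
    eval_seed: int = 424242
    early_stopping_patience: int | None = None


def run_round(clients: list[FedClient], server_state: ServerState,
              round_config: RoundConfig) -> tuple[ServerState, list[dict]]:
    """One synchronous federated round over in-process clients.

    Broadcast current global (if any) -> local training -> deterministic
    evaluation -> package -> plan -> aggregate -> broadcast.  A client whose
    local phase raises is excluded from the plan and logged, not fatal.
    """
    if not clients:
        raise ValidationError("need at least one client")
    if server_state.global_params is not None:
        for c in clients:
            c.agent.set_params(server_state.global_params)

    updates, rows, round_start = [], [], {}
    for c in clients:
        start = (server_state.global_params.vector.copy()
                 if server_state.global_params is not None
                 else c.agent.get_params().vector.copy())
        round_start[c.client_id] = start
        n_before = c.agent.transitions_collected
        try:
            _, log = train_local(
                c.agent, c.env, round_config.local_epochs,
                round_config.steps_per_epoch,
                val_env=c.val_env,
                updates_per_epoch=round_config.updates_per_epoch,
                early_stopping_patience=round_config.early_stopping_patience)
            eval_env = c.val_env if c.val_env is not None else c.env
            trace, eval_return = evaluate_policy(c.agent, eval_env,
                                                 seed=round_config.eval_seed)
            update = package_update(
                c.agent, trace, c.client_id,
                num_samples=c.agent.transitions_collected - n_before,
                reward_config=getattr(eval_env, "reward_config", None))
        except Exception as exc:  # noqa: BLE001 - client failure is non-fatal
            rows.append({"round": server_state.round, "client": c.client_id,
                         "failed": True, "error": repr(exc)})
            continue
        from .metrics import glycemic_report
        rep = glycemic_report(trace)
        delta = update.params.vector - round_start[c.client_id]
        rows.append({
            "round": server_state.round, "client": c.client_id, "failed": False,
            "n_samples": update.num_samples, "mean_risk": update.mean_risk,
            "eval_return": eval_return, "val_tir": rep.tir,
            "update_delta_norm": float(np.linalg.norm(delta)),
            "final_epoch_log": log[-1] if log else {},
        })
        updates.append(update)

    if not updates:
        raise ValidationError("all clients failed this round")
    plan = make_plan(updates, round_config.strategy, round_config.lambda_risk)
    new_global = aggregate(updates, plan)
    for row, w in zip([r for r in rows if not r.get("failed")], plan.weights):
        row["weight"] = float(w)
    for c in clients:
        c.agent.set_params(new_global)

    # Score the broadcast global policy on every client's validation
    # environment; this is the per-round validation curve.
    from .metrics import glycemic_report
    risks, tirs = [], []
    for c in clients:
        env = c.val_env if c.val_env is not None else c.env
        trace, _ = evaluate_policy(c.agent, env, seed=round_config.eval_seed)
        risks.append(float(np.mean(bg_risk(np.asarray(trace.plasma_glucose)))))
        tirs.append(glycemic_report(trace).tir)
    rows.append({"round": server_state.round, "client": "_global", "failed": False,
                 "val_mean_risk": float(np.mean(risks)),
                 "val_tir": float(np.mean(tirs))})

    server_state.global_params = new_global
    server_state.round += 1
    return server_state, rows
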