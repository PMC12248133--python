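"""Multiobjective reward: glucose deviation, insulin overuse, stability, glycemic risk.

The per-transition reward is a weighted sum of four nonpositive components

    r = alpha * deviation + beta * insulin + gamma * stability + eta * risk

with hypoglycemia weighted more heavily than an equal hyperglycemic deviation
(safety asymmetry).  The risk component uses the standard blood-glucose risk
function of Kovatchev/Magni type,

    risk(g) = 10 * [1.509 * ((ln g)^1.084 - 5.381)]^2,   g clamped to [20, 600]

which is ~0 near 112.5 mg/dL and rises toward both glycemic extremes, more
steeply on the hypoglycemic side.  Exploration pressure is *not* a reward
term here: it enters through the soft actor-critic entropy temperature in the
agent's objective.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .exceptions import ConfigError, ValidationError

#: Glucose value (mg/dL) at which the risk function is exactly zero.
RISK_ROOT: float = float(np.exp(5.381 ** (1.0 / 1.084)))


def bg_risk(glucose):
    """Blood-glucose risk score, vectorized; nonnegative, zero at ``RISK_ROOT``."""
    g = np.asarray(glucose, dtype=float)
    if np.any(g <= 0):
        raise ValidationError("glucose must be strictly positive")
    g = np.clip(g, 20.0, 600.0)
    f = 1.509 * (np.log(g) ** 1.084 - 5.381)
    out = 10.0 * f * f
    return float(out) if np.isscalar(glucose) or out.ndim == 0 else out


@dataclass(frozen=True)
class RewardConfig:
    alpha: float = 1.0                    # glucose-deviation weight
    beta: float = 0.1                     # insulin-use weight
    gamma: float = 0.5                    # stability weight
    eta: float = 1.0                      # risk weight
    target_glucose: float = 112.5         # mg/dL
    hypo_threshold: float = 70.0          # mg/dL
    hyper_threshold: float = 180.0        # mg/dL
    hypo_penalty_multiplier: float = 3.0  # >= 1
    deviation_normalizer: float = 100.0   # mg/dL
    stability_normalizer: float = 50.0    # mg/dL per step
    risk_normalizer: float = 100.0        # risk units
    max_insulin_rate: float = 3.0         # U/h; a_max of the acting pump


@dataclass(frozen=True)
class RewardBreakdown:
    deviation_term: float  # <= 0
    insulin_term: float    # <= 0
    stability_term: float  # <= 0 (small magnitude when stable)
    risk_term: float       # <= 0
    total: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def validate_config(config: RewardConfig | dict | None = None) -> RewardConfig:
    """Fill defaults, check invariants; raise ``ConfigError`` naming the field."""
    if config is None:
        config = RewardConfig()
    elif isinstance(config, dict):
        known = {f.name for f in fields(RewardConfig)}
        unknown = set(config) - known
        if unknown:
            raise ConfigError(f"unknown reward config field(s): {sorted(unknown)}")
        config = RewardConfig(**config)
    for name in ("alpha", "beta", "gamma", "eta"):
        if getattr(config, name) < 0:
            raise ConfigError(f"reward weight {name} must be >= 0")
    if not (config.hypo_threshold < config.target_glucose < config.hyper_threshold):
        raise ConfigError(
            "require hypo_threshold < target_glucose < hyper_threshold "
            f"(got {config.hypo_threshold}, {config.target_glucose}, {config.hyper_threshold})"
        )
    if config.hypo_penalty_multiplier < 1:
        raise ConfigError("hypo_penalty_multiplier must be >= 1")
    for name in ("deviation_normalizer", "stability_normalizer", "risk_normalizer",
                 "max_insulin_rate"):
        if getattr(config, name) <= 0:
            raise ConfigError(f"{name} must be > 0")
    return config


def compute_reward(prev_obs, action, new_bg: float, prev_bg: float,
                   config: RewardConfig) -> RewardBreakdown:
    """Reward for one 5-minute transition.

    ``prev_obs`` is accepted for interface completeness (the components are
    functions of the glucose transition and the delivered rate alone).
    """
    config = validate_config(config)
    if new_bg <= 0 or prev_bg <= 0:
        raise ValidationError("glucose values must be positive")
    rate = getattr(action, "rate", action)

    deviation = -abs(new_bg - config.target_glucose) / config.deviation_normalizer
    if new_bg < config.hypo_threshold:
        deviation *= config.hypo_penalty_multiplier
    insulin = -rate / config.max_insulin_rate
    stability = -abs(new_bg - prev_bg) / config.stability_normalizer
    risk = -bg_risk(new_bg) / config.risk_normalizer
    total = (config.alpha * deviation + config.beta * insulin
             + config.gamma * stability + config.eta * risk)
    return RewardBreakdown(
        deviation_term=float(deviation),
        insulin_term=float(insulin),
        stability_term=float(stability),
        risk_term=float(risk),
        total=float(total),
    )


def with_pump_limit(config: RewardConfig, max_rate: float) -> RewardConfig:
    """Copy of ``config`` with the insulin normalizer set to a pump's a_max."""
    return replace(config, max_insulin_rate=float(max_rate))
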