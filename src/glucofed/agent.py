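"""Recurrent soft actor-critic over CGM/insulin/carb histories.

The actor and twin critics share an architecture: a stack of GRU layers over
the per-step observation features, followed by fully connected heads (with
dropout during training only).  Actions are a single continuous basal rate,
produced by a tanh-squashed Gaussian and scaled to [0, a_max].  Training uses
the entropy-regularized soft Bellman target with the minimum of the two
target critics, Polyak-averaged target networks, and optional automatic
tuning of the entropy temperature toward a target entropy of -(action dim).

Observation sequences are replayed as fixed-length windows that never cross
episode boundaries; a short burn-in prefix warms the recurrent state and is
excluded from the losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .envs import InsulinAction, Observation
from .exceptions import ConfigError, NumericsError
from .nn import Adam, GRUCell, Linear, Parameter, Tensor, concat, minimum

LOG_STD_MIN, LOG_STD_MAX = -5.0, 2.0
_LOG2 = math.log(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Normalization constants for observation features.
CGM_CENTER, CGM_SCALE = 140.0, 100.0
CARB_SCALE = 60.0


@dataclass(frozen=True)
class AgentConfig:
    obs_dim: int = 38            # 3 * k_history + 2 for k = 12
    gru_layers: int = 2
    hidden_units: int = 128
    fc_units: int = 64
    batch_size: int = 256
    sequence_length: int = 72    # 6 h of 5-min steps
    burn_in: int = 12
    discount: float = 0.99
    entropy_temperature: float = 0.2
    auto_entropy: bool = True
    target_entropy: float = -1.0
    actor_lr: float = 3e-4
    critic_lr: float = 3e-4
    temperature_lr: float = 3e-4
    polyak_factor: float = 0.005
    dropout_rate: float = 0.1
    epochs: int = 300
    replay_capacity: int = 200_000
    min_buffer: int = 512
    updates_per_epoch: int = 50
    action_scale: float = 1.0    # a_max of this client's pump, U/h

    def validate(self) -> "AgentConfig":
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.replay_capacity < self.batch_size * self.sequence_length:
            raise ConfigError("replay_capacity must cover batch_size * sequence_length")
        if not (0.0 < self.discount < 1.0):
            raise ConfigError("discount must lie in (0, 1)")
        if not (0.0 <= self.polyak_factor <= 1.0):
            raise ConfigError("polyak_factor must lie in [0, 1]")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.burn_in >= self.sequence_length:
            raise ConfigError("burn_in must be < sequence_length")
        if self.entropy_temperature < 0:
            raise ConfigError("entropy_temperature must be >= 0")
        return self


@dataclass(frozen=True)
class PolicyParams:
    """All learnable parameters as one flat vector plus a slice index."""

    vector: np.ndarray
    index: tuple[tuple[str, tuple[int, ...], int], ...]  # (name, shape, offset)

    def slice(self, name: str) -> np.ndarray:
        for nm, shape, off in self.index:
            if nm == name:
                size = int(np.prod(shape)) if shape else 1
                return self.vector[off:off + size].reshape(shape)
        raise KeyError(name)


@dataclass
class ReplaySequence:
    """One contiguous window from a single episode."""

    obs: np.ndarray   # (T+1, obs_dim)
    act: np.ndarray   # (T,) normalized to [0, 1]
    rew: np.ndarray   # (T,)
    done: np.ndarray  # (T,)


class ReplayBuffer:
    """Episode-segment store; sampled windows never cross segment boundaries."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self.segments: list[dict] = []
        self.total = 0

    def add_segment(self, obs: np.ndarray, act: np.ndarray, rew: np.ndarray,
                    done: np.ndarray) -> None:
        n = len(act)
        if n == 0:
            return
        self.segments.append({"obs": obs, "act": act, "rew": rew, "done": done})
        self.total += n
        while self.total > self.capacity and len(self.segments) > 1:
            self.total -= len(self.segments.pop(0)["act"])

    def sample(self, batch_size: int, seq_len: int,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
        eligible = [s for s in self.segments if len(s["act"]) >= seq_len]
        if not eligible:
            eligible = [max(self.segments, key=lambda s: len(s["act"]))]
            seq_len = len(eligible[0]["act"])
        obs_b, act_b, rew_b, done_b = [], [], [], []
        for _ in range(batch_size):
            seg = eligible[int(rng.integers(len(eligible)))]
            start = int(rng.integers(len(seg["act"]) - seq_len + 1))
            obs_b.append(seg["obs"][start:start + seq_len + 1])
            act_b.append(seg["act"][start:start + seq_len])
            rew_b.append(seg["rew"][start:start + seq_len])
            done_b.append(seg["done"][start:start + seq_len])
        return {"obs": np.stack(obs_b), "act": np.stack(act_b),
                "rew": np.stack(rew_b), "done": np.stack(done_b)}


def featurize(obs: Observation, action_scale: float) -> np.ndarray:
    """Observation -> flat feature vector of length 3k + 2."""
    tod = 2.0 * math.pi * obs.time_of_day / 1440.0
    return np.concatenate([
        (np.asarray(obs.cgm_history) - CGM_CENTER) / CGM_SCALE,
        np.asarray(obs.insulin_history) / max(action_scale, 1e-9),
        np.asarray(obs.carb_history) / CARB_SCALE,
        [math.sin(tod), math.cos(tod)],
    ])


class _GRUStack:
    def __init__(self, n_in, n_hidden, n_layers, rng):
        self.cells = [GRUCell(n_in if i == 0 else n_hidden, n_hidden, rng)
                      for i in range(n_layers)]
        self.n_hidden = n_hidden

    def step_np(self, x: np.ndarray, hidden: list[np.ndarray]) -> tuple[np.ndarray, list]:
        new = []
        for cell, h in zip(self.cells, hidden):
            x = cell.forward_np(x, h)
            new.append(x)
        return x, new

    def run_np(self, xs: np.ndarray) -> np.ndarray:
        """(B, T, D) -> (B, T, H) without building a graph."""
        b, t, _ = xs.shape
        hidden = [np.zeros((b, self.n_hidden)) for _ in self.cells]
        feats = np.empty((b, t, self.n_hidden))
        for i in range(t):
            out, hidden = self.step_np(xs[:, i, :], hidden)
            feats[:, i, :] = out
        return feats

    def run_graph(self, xs: np.ndarray) -> list[Tensor]:
        """(B, T, D) -> list of T feature Tensors (B, H) with gradients."""
        b, t, _ = xs.shape
        hidden = [Tensor(np.zeros((b, self.n_hidden))) for _ in self.cells]
        feats = []
        for i in range(t):
            x = Tensor(xs[:, i, :])
            new_hidden = []
            for cell, h in zip(self.cells, hidden):
                x = cell(x, h)
                new_hidden.append(x)
            hidden = new_hidden
            feats.append(x)
        return feats

    def parameters(self):
        return [p for c in self.cells for p in c.parameters()]


class _Actor:
    def __init__(self, cfg: AgentConfig, rng):
        self.gru = _GRUStack(cfg.obs_dim, cfg.hidden_units, cfg.gru_layers, rng)
        self.fc = Linear(cfg.hidden_units, cfg.fc_units, rng)
        # Small head init: the untrained mode sits at mid-range (the pump's
        # programmed basal when a_max = 2 x basal).
        self.mean = Linear(cfg.fc_units, 1, rng, weight_scale=0.01)
        self.log_std = Linear(cfg.fc_units, 1, rng, weight_scale=0.01)

    def heads_np(self, feat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hid = np.maximum(self.fc.forward_np(feat), 0.0)
        mu = self.mean.forward_np(hid)
        raw = self.log_std.forward_np(hid)
        ls = LOG_STD_MIN + 0.5 * (LOG_STD_MAX - LOG_STD_MIN) * (np.tanh(raw) + 1.0)
        return mu, ls

    def heads_graph(self, feat: Tensor, dropout_mask=None) -> tuple[Tensor, Tensor]:
        hid = self.fc(feat).relu()
        if dropout_mask is not None:
            hid = hid * Tensor(dropout_mask)
        mu = self.mean(hid)
        raw = self.log_std(hid)
        ls = LOG_STD_MIN + 0.5 * (LOG_STD_MAX - LOG_STD_MIN) * (raw.tanh() + 1.0)
        return mu, ls

    def parameters(self):
        return (self.gru.parameters() + self.fc.parameters()
                + self.mean.parameters() + self.log_std.parameters())


class _Critic:
    def __init__(self, cfg: AgentConfig, rng):
        self.gru = _GRUStack(cfg.obs_dim, cfg.hidden_units, cfg.gru_layers, rng)
        self.q1 = Linear(cfg.hidden_units + 1, cfg.fc_units, rng)
        self.q2 = Linear(cfg.fc_units, 1, rng)

    def q_np(self, feat: np.ndarray, act01: np.ndarray) -> np.ndarray:
        x = np.concatenate([feat, act01], axis=-1)
        return self.q2.forward_np(np.maximum(self.q1.forward_np(x), 0.0))

    def q_graph(self, feat: Tensor, act01: Tensor, dropout_mask=None) -> Tensor:
        hid = self.q1(concat([feat, act01], axis=-1)).relu()
        if dropout_mask is not None:
            hid = hid * Tensor(dropout_mask)
        return self.q2(hid)

    def q_graph_detached(self, feat_const: np.ndarray, act01: Tensor) -> Tensor:
        """Q with critic weights frozen; gradient flows through the action only."""
        w1, b1 = Tensor(self.q1.W.data), Tensor(self.q1.b.data)
        w2, b2 = Tensor(self.q2.W.data), Tensor(self.q2.b.data)
        hid = (concat([Tensor(feat_const), act01], axis=-1) @ w1 + b1).relu()
        return hid @ w2 + b2

    def parameters(self):
        return self.gru.parameters() + self.q1.parameters() + self.q2.parameters()


def _squash_logprob_np(u, mu, log_std):
    std = np.exp(log_std)
    log_n = -0.5 * ((u - mu) / std) ** 2 - log_std - _LOG_SQRT_2PI
    # log(1 - tanh(u)^2), stable; density over the [0, 1]-normalized action
    log_jac = 2.0 * (_LOG2 - u - np.logaddexp(0.0, -2.0 * u)) - _LOG2
    return log_n - log_jac


class SACAgent:
    """One client's learner.  All randomness flows from the construction seed."""

    def __init__(self, config: AgentConfig, seed: int):
        self.config = config.validate()
        root = np.random.SeedSequence(seed)
        init_ss, act_ss, train_ss, env_ss = root.spawn(4)
        init_rng = np.random.default_rng(init_ss)
        self._action_rng = np.random.default_rng(act_ss)
        self._train_rng = np.random.default_rng(train_ss)
        self._env_seed_rng = np.random.default_rng(env_ss)

        self.actor = _Actor(config, init_rng)
        self.critic1 = _Critic(config, init_rng)
        self.critic2 = _Critic(config, init_rng)
        self.target1 = _Critic(config, init_rng)
        self.target2 = _Critic(config, init_rng)
        self._copy_params(self.critic1, self.target1)
        self._copy_params(self.critic2, self.target2)
        self.log_alpha = Parameter(np.array(math.log(max(config.entropy_temperature, 1e-8))))

        self.opt_actor = Adam(self.actor.parameters(), lr=config.actor_lr)
        self.opt_critic = Adam(self.critic1.parameters() + self.critic2.parameters(),
                               lr=config.critic_lr)
        self.opt_temp = Adam([self.log_alpha], lr=config.temperature_lr)

        self.buffer = ReplayBuffer(config.replay_capacity)
        self.transitions_collected = 0
        self.updates_done = 0
        self._registry = self._build_registry()

    # -- parameter plumbing -------------------------------------------------

    @staticmethod
    def _copy_params(src: _Critic, dst: _Critic) -> None:
        for p_src, p_dst in zip(src.parameters(), dst.parameters()):
            p_dst.data = p_src.data.copy()

    def _build_registry(self) -> list[tuple[str, Parameter]]:
        reg = []
        nets = [("actor", self.actor), ("critic1", self.critic1),
                ("critic2", self.critic2), ("target1", self.target1),
                ("target2", self.target2)]
        for name, net in nets:
            for i, p in enumerate(net.parameters()):
                reg.append((f"{name}.{i}", p))
        reg.append(("log_alpha", self.log_alpha))
        return reg

    def get_params(self) -> PolicyParams:
        parts, index, off = [], [], 0
        for name, p in self._registry:
            flat = p.data.ravel()
            parts.append(flat)
            index.append((name, p.data.shape, off))
            off += flat.size
        return PolicyParams(vector=np.concatenate(parts), index=tuple(index))

    def set_params(self, params: PolicyParams) -> None:
        expected = sum(p.data.size for _, p in self._registry)
        if params.vector.size != expected:
            raise ConfigError(
                f"parameter vector length {params.vector.size} != expected {expected}")
        off = 0
        for _, p in self._registry:
            size = p.data.size
            p.data = params.vector[off:off + size].reshape(p.data.shape).copy()
            off += size

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha.data))

    # -- acting -------------------------------------------------------------

    def initial_hidden(self) -> list[np.ndarray]:
        return [np.zeros(self.config.hidden_units)
                for _ in range(self.config.gru_layers)]

    def select_action(self, obs: Observation, hidden: list[np.ndarray] | None = None,
                      deterministic: bool = False):
        """Map one observation to an insulin rate in [0, action_scale].

        Returns ``(InsulinAction, hidden')``; deterministic mode returns the
        squashed policy mode.
        """
        if hidden is None:
            hidden = self.initial_hidden()
        x = featurize(obs, self.config.action_scale)[None, :]
        hs = [h[None, :] for h in hidden]
        feat, new_hs = self.actor.gru.step_np(x, hs)
        mu, log_std = self.actor.heads_np(feat)
        if deterministic:
            u = mu
        else:
            u = mu + np.exp(log_std) * self._action_rng.standard_normal(mu.shape)
        a01 = 0.5 * (np.tanh(u) + 1.0)
        rate = float(a01[0, 0]) * self.config.action_scale
        return InsulinAction(rate), [h[0] for h in new_hs]

    # -- learning -----------------------------------------------------------

    def _next_action_logpi_np(self, obs_next: np.ndarray, eps: np.ndarray):
        """Policy sample and log-prob at the next observations (no graph)."""
        feats = self.actor.gru.run_np(obs_next)  # (B, T, H) -- includes step 0
        b, t, h = feats.shape
        flat = feats.reshape(b * t, h)
        mu, log_std = self.actor.heads_np(flat)
        u = mu + np.exp(log_std) * eps.reshape(b * t, 1)
        a01 = 0.5 * (np.tanh(u) + 1.0)
        logpi = _squash_logprob_np(u, mu, log_std)
        return a01.reshape(b, t), logpi.reshape(b, t)

    def bellman_targets(self, batch: dict[str, np.ndarray],
                        next_eps: np.ndarray | None = None) -> np.ndarray:
        """Soft Bellman targets y_t for a sampled window (B, T).

        y_t = r_t + gamma * (1 - done_t) * (min_i Qbar_i(o_{t+1}, a') - alpha * log pi(a'))
        with a' drawn from the current policy.  ``next_eps`` fixes the policy
        noise (B, T) for reproducible comparison against an external oracle.
        """
        obs, rew, done = batch["obs"], batch["rew"], batch["done"]
        b, t = rew.shape
        if next_eps is None:
            next_eps = self._train_rng.standard_normal((b, t))
        # Policy over the full sequence; positions 1..T are the next-obs steps.
        eps_full = np.concatenate([np.zeros((b, 1)), next_eps], axis=1)
        a_next, logpi_next = self._next_action_logpi_np(obs, eps_full)
        a_next, logpi_next = a_next[:, 1:], logpi_next[:, 1:]

        q_min = None
        for tgt in (self.target1, self.target2):
            feats = tgt.gru.run_np(obs)[:, 1:, :]
            q = tgt.q_np(feats.reshape(b * t, -1),
                         a_next.reshape(b * t, 1)).reshape(b, t)
            q_min = q if q_min is None else np.minimum(q_min, q)
        return rew + self.config.discount * (1.0 - done) * (
            q_min - self.alpha * logpi_next)

    def _dropout_mask(self, shape) -> np.ndarray | None:
        p = self.config.dropout_rate
        if p <= 0:
            return None
        return (self._train_rng.random(shape) >= p) / (1.0 - p)

    def update(self, batch: dict[str, np.ndarray]) -> dict[str, float]:
        """One gradient step for critics, actor, and (optionally) temperature."""
        cfg = self.config
        obs, act, rew = batch["obs"], batch["act"], batch["rew"]
        b, t = rew.shape
        burn = min(cfg.burn_in, max(t - 1, 0))
        valid = np.zeros((b, t, 1))
        valid[:, burn:, :] = 1.0
        n_valid = valid.sum()

        y = self.bellman_targets(batch)[:, :, None]  # (B, T, 1)

        # --- critic phase ---
        critic_loss = Tensor(0.0)
        for critic in (self.critic1, self.critic2):
            feats = critic.gru.run_graph(obs[:, :t, :])
            mask = self._dropout_mask((t * b, cfg.fc_units))
            flat = concat(feats, axis=0)  # (T*B, H) time-major
            act_tm = np.transpose(act[:, :, None], (1, 0, 2)).reshape(t * b, 1)
            q = critic.q_graph(flat, Tensor(act_tm), dropout_mask=mask)
            y_tm = np.transpose(y, (1, 0, 2)).reshape(t * b, 1)
            v_tm = np.transpose(valid, (1, 0, 2)).reshape(t * b, 1)
            err = (q - Tensor(y_tm)) * Tensor(v_tm)
            critic_loss = critic_loss + (err ** 2).sum() * (1.0 / n_valid)
        self.opt_critic.zero_grad()
        self.opt_actor.zero_grad()
        critic_loss.backward()
        self.opt_critic.step()

        # --- actor phase ---
        feats = self.actor.gru.run_graph(obs[:, :t, :])
        flat = concat(feats, axis=0)  # (T*B, H)
        amask = self._dropout_mask((t * b, cfg.fc_units))
        mu, log_std = self.actor.heads_graph(flat, dropout_mask=amask)
        eps = self._train_rng.standard_normal((t * b, 1))
        std = log_std.exp()
        u = mu + std * Tensor(eps)
        tanh_u = u.tanh()
        a01 = 0.5 * (tanh_u + 1.0)
        log_n = (-0.5) * ((u - mu) / std) ** 2 - log_std - _LOG_SQRT_2PI
        log_jac = 2.0 * (_LOG2 - u - ((-2.0) * u).softplus()) - _LOG2
        logpi = log_n - log_jac

        q_min = None
        for critic in (self.critic1, self.critic2):
            feat_c = critic.gru.run_np(obs[:, :t, :])
            feat_tm = np.transpose(feat_c, (1, 0, 2)).reshape(t * b, -1)
            qc = critic.q_graph_detached(feat_tm, a01)
            q_min = qc if q_min is None else minimum(q_min, qc)
        v_tm = np.transpose(valid, (1, 0, 2)).reshape(t * b, 1)
        actor_loss = ((self.alpha * logpi - q_min) * Tensor(v_tm)).sum() * (1.0 / n_valid)
        self.opt_actor.zero_grad()
        self.opt_critic.zero_grad()
        actor_loss.backward()
        self.opt_actor.step()

        # --- temperature phase ---
        if cfg.auto_entropy:
            mean_logpi = float((logpi.data * v_tm).sum() / n_valid)
            temp_loss = (-1.0) * self.log_alpha * (mean_logpi + cfg.target_entropy)
            self.opt_temp.zero_grad()
            temp_loss.backward()
            self.opt_temp.step()
            temp_loss_val = float(temp_loss.data)
        else:
            temp_loss_val = 0.0

        # --- Polyak averaging ---
        rho = cfg.polyak_factor
        for critic, target in ((self.critic1, self.target1), (self.critic2, self.target2)):
            for p, pt in zip(critic.parameters(), target.parameters()):
                pt.data = (1.0 - rho) * pt.data + rho * p.data

        losses = {"critic": float(critic_loss.data), "actor": float(actor_loss.data),
                  "temperature": temp_loss_val}
        for k, v in losses.items():
            if not np.isfinite(v):
                raise NumericsError(f"non-finite {k} loss (alpha={self.alpha:.3g})")
        self.updates_done += 1
        return losses

    # -- experience collection & local training -----------------------------

    def collect(self, env, n_steps: int, carry: dict | None = None) -> dict:
        """Run the stochastic policy for ``n_steps`` env steps, filling the buffer.

        ``carry`` holds a paused episode so collection can resume mid-episode
        across epochs; completed-episode returns accrue in ``carry['returns']``.
        """
        scale = self.config.action_scale
        if carry is None or carry.get("obs") is None:
            seed = int(self._env_seed_rng.integers(2 ** 31 - 1))
            obs = env.reset(seed)
            carry = {"obs": obs, "hidden": self.initial_hidden(),
                     "seq": [featurize(obs, scale)], "act": [], "rew": [],
                     "done": [], "ret": 0.0, "returns": list((carry or {}).get("returns", []))}
        for _ in range(n_steps):
            action, carry["hidden"] = self.select_action(carry["obs"], carry["hidden"])
            obs, r, done, _ = env.step(action)
            carry["seq"].append(featurize(obs, scale))
            carry["act"].append(action.rate / max(scale, 1e-9))
            carry["rew"].append(r)
            carry["done"].append(float(done))
            carry["ret"] += r
            carry["obs"] = obs
            self.transitions_collected += 1
            if done:
                self._flush(carry)
                carry["returns"].append(carry["ret"])
                seed = int(self._env_seed_rng.integers(2 ** 31 - 1))
                obs = env.reset(seed)
                carry.update(obs=obs, hidden=self.initial_hidden(),
                             seq=[featurize(obs, scale)], act=[], rew=[],
                             done=[], ret=0.0)
        return carry

    def _flush(self, carry: dict) -> None:
        if carry["act"]:
            self.buffer.add_segment(np.stack(carry["seq"]), np.array(carry["act"]),
                                    np.array(carry["rew"]), np.array(carry["done"]))

    def sample_batch(self) -> dict[str, np.ndarray]:
        return self.buffer.sample(self.config.batch_size,
                                  self.config.sequence_length, self._train_rng)


def evaluate_policy(agent: SACAgent, env, seed: int, deterministic: bool = True):
    """Roll one full episode; returns (EpisodeTrace, total return)."""
    obs = env.reset(seed)
    hidden = agent.initial_hidden()
    total, done = 0.0, False
    while not done:
        action, hidden = agent.select_action(obs, hidden, deterministic=deterministic)
        obs, r, done, _ = env.step(action)
        total += r
    return env.trace, total


def train_local(agent: SACAgent, env, epochs: int, steps_per_epoch: int,
                val_env=None, updates_per_epoch: int | None = None,
                early_stopping_patience: int | None = None) -> tuple[SACAgent, list[dict]]:
    """Alternate experience collection and SAC updates on one client.

    Per epoch: collect ``steps_per_epoch`` transitions, then run
    ``updates_per_epoch`` gradient steps once the buffer holds at least
    ``min_buffer`` transitions.  If ``val_env`` is given, the deterministic
    policy is scored on it every epoch (return, time-in-range, mean risk) and
    early stopping halts training after ``early_stopping_patience`` epochs
    without improvement in validation mean risk.
    """
    if epochs < 1:
        raise ConfigError("epochs must be >= 1")
    from .metrics import glycemic_report
    from .reward import bg_risk

    n_updates = (agent.config.updates_per_epoch
                 if updates_per_epoch is None else updates_per_epoch)
    log: list[dict] = []
    carry: dict | None = None
    best_risk, stale = np.inf, 0
    for epoch in range(epochs):
        carry = agent.collect(env, steps_per_epoch, carry)
        losses = {"critic": np.nan, "actor": np.nan, "temperature": np.nan}
        if agent.buffer.total >= min(agent.config.min_buffer, agent.config.replay_capacity):
            for _ in range(n_updates):
                losses = agent.update(agent.sample_batch())
        returns = carry["returns"]
        entry = {
            "epoch": epoch,
            "steps_collected": agent.transitions_collected,
            "buffer_size": agent.buffer.total,
            "mean_return": float(np.mean(returns)) if returns else np.nan,
            "alpha": agent.alpha,
            **{f"loss_{k}": v for k, v in losses.items()},
        }
        carry["returns"] = []
        if val_env is not None:
            trace, val_ret = evaluate_policy(agent, val_env, seed=10_000 + epoch)
            rep = glycemic_report(trace)
            entry.update(val_return=val_ret, val_tir=rep.tir,
                         val_mean_risk=float(np.mean(bg_risk(
                             np.asarray(trace.plasma_glucose)))))
            if early_stopping_patience is not None:
                if entry["val_mean_risk"] < best_risk - 1e-9:
                    best_risk, stale = entry["val_mean_risk"], 0
                else:
                    stale += 1
                if stale >= early_stopping_patience:
                    log.append(entry)
                    break
        log.append(entry)
    if carry is not None:
        agent._flush(carry)
        carry.update(seq=[], act=[], rew=[], done=[], obs=None)
    return agent, log
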