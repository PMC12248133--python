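"""Recurrent SAC: initialization, action bounds, Bellman targets, learning harnesses."""

import math

import numpy as np
import pytest

from glucofed.agent import (AgentConfig, SACAgent, featurize, train_local,
                            _squash_logprob_np)
from glucofed.envs import Observation
from glucofed.nn import GRUCell, Linear

from conftest import random_batch, tiny_agent_config


def obs_of(x: float, k: int = 1) -> Observation:
    return Observation(cgm_history=np.full(k, 140.0 + 100.0 * x),
                       insulin_history=np.zeros(k),
                       carb_history=np.zeros(k), time_of_day=0.0)


class ToyDriftEnv:
    """1-dim 'hold the setpoint' plant: x' = 0.9 x + 0.8 (a - 0.3) + noise.

    Reward is -x**2; the optimal stationary action is 0.3, away from the
    policy's initial mode of 0.5, so improvement is measurable.
    """

    def __init__(self, episode_len=40, noise=0.05):
        self.episode_len = episode_len
        self.noise = noise
        self.reward_config = None

    def reset(self, seed):
        self.rng = np.random.default_rng(seed)
        self.x = float(self.rng.uniform(-0.5, 0.5))
        self.n = 0
        return obs_of(self.x)

    def step(self, action):
        a = float(np.clip(getattr(action, "rate", action), 0.0, 1.0))
        self.x = 0.9 * self.x + 0.8 * (a - 0.3) + self.noise * self.rng.standard_normal()
        self.n += 1
        r = -self.x ** 2
        return obs_of(self.x), r, self.n >= self.episode_len, {}


def mc_return(agent, env, n_episodes=20, seed0=100):
    totals = []
    for i in range(n_episodes):
        obs = env.reset(seed0 + i)
        hidden, total, done = agent.initial_hidden(), 0.0, False
        while not done:
            action, hidden = agent.select_action(obs, hidden, deterministic=True)
            obs, r, done, _ = env.step(action)
            total += r
        totals.append(total)
    return float(np.mean(totals))


class TestInit:
    def test_parameter_count_matches_architecture(self):
        cfg = AgentConfig()  # 2 GRU layers x 128, obs_dim 38, fc 64
        agent = SACAgent(cfg, seed=0)
        gru = (GRUCell.param_count(38, 128) + GRUCell.param_count(128, 128))
        actor = gru + Linear.param_count(128, 64) + 2 * Linear.param_count(64, 1)
        critic = gru + Linear.param_count(129, 64) + Linear.param_count(64, 1)
        expected = actor + 4 * critic + 1  # critics, targets, log_alpha
        assert agent.get_params().vector.size == expected

    def test_targets_equal_critics_at_init(self, tiny_agent):
        for c, t in ((tiny_agent.critic1, tiny_agent.target1),
                     (tiny_agent.critic2, tiny_agent.target2)):
            for pc, pt in zip(c.parameters(), t.parameters()):
                np.testing.assert_array_equal(pc.data, pt.data)

    def test_same_seed_identical_params(self):
        a = SACAgent(tiny_agent_config(), seed=3).get_params()
        b = SACAgent(tiny_agent_config(), seed=3).get_params()
        np.testing.assert_array_equal(a.vector, b.vector)

    def test_params_roundtrip_lossless(self, tiny_agent):
        params = tiny_agent.get_params()
        tiny_agent.set_params(params)
        np.testing.assert_array_equal(tiny_agent.get_params().vector, params.vector)
        np.testing.assert_allclose(params.slice("log_alpha"),
                                   tiny_agent.log_alpha.data)


class TestSelectAction:
    def test_action_bound_never_violated(self):
        agent = SACAgent(tiny_agent_config(action_scale=2.5), seed=1)
        obs = obs_of(0.0)
        hidden = None
        for _ in range(2000):
            action, hidden = agent.select_action(obs, hidden)
            assert 0.0 <= action.rate <= 2.5

    def test_bound_holds_over_1e5_policy_samples(self, tiny_agent):
        """Squashed-Gaussian sampling cannot leave [0, a_max] anywhere in
        observation space (vectorized over 10^5 draws)."""
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((200, tiny_agent.config.obs_dim)) * 3
        h, _ = tiny_agent.actor.gru.step_np(
            feats, [np.zeros((200, tiny_agent.config.hidden_units))])
        mu, log_std = tiny_agent.actor.heads_np(h)
        eps = rng.standard_normal((200, 500))
        a01 = 0.5 * (np.tanh(mu + np.exp(log_std) * eps) + 1.0)
        assert a01.size == 100_000
        assert np.all((a01 >= 0.0) & (a01 <= 1.0))

    def test_deterministic_repeatable(self, tiny_agent):
        obs = obs_of(0.3)
        a1, _ = tiny_agent.select_action(obs, None, deterministic=True)
        a2, _ = tiny_agent.select_action(obs, None, deterministic=True)
        assert a1.rate == a2.rate

    def test_stochastic_has_variance(self, tiny_agent):
        obs = obs_of(0.1)
        draws = [tiny_agent.select_action(obs, None)[0].rate for _ in range(1000)]
        assert np.std(draws) > 0

    def test_hidden_state_advances(self, tiny_agent):
        obs = obs_of(0.5)
        _, h1 = tiny_agent.select_action(obs, None, deterministic=True)
        _, h2 = tiny_agent.select_action(obs, h1, deterministic=True)
        assert not all(np.array_equal(a, b) for a, b in zip(h1, h2))


class TestUpdate:
    def test_polyak_zero_freezes_targets(self):
        agent = SACAgent(tiny_agent_config(polyak_factor=0.0), seed=2)
        before = [p.data.copy() for p in agent.target1.parameters()]
        agent.update(random_batch(np.random.default_rng(0)))
        for b, p in zip(before, agent.target1.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_polyak_one_copies_critics(self):
        agent = SACAgent(tiny_agent_config(polyak_factor=1.0), seed=2)
        agent.update(random_batch(np.random.default_rng(0)))
        for pc, pt in zip(agent.critic1.parameters(), agent.target1.parameters()):
            np.testing.assert_array_equal(pc.data, pt.data)

    def test_overfit_one_batch_reduces_critic_loss(self):
        agent = SACAgent(tiny_agent_config(batch_size=4, polyak_factor=0.0), seed=4)
        batch = random_batch(np.random.default_rng(1))
        first = agent.update(batch)["critic"]
        last = None
        for _ in range(200):
            last = agent.update(batch)["critic"]
        assert last < first

    def test_losses_finite(self, tiny_agent):
        losses = tiny_agent.update(random_batch(np.random.default_rng(2)))
        assert all(np.isfinite(v) for v in losses.values())


class TestBellmanOracle:
    def test_targets_match_handrolled_reimplementation(self):
        """Soft Bellman targets vs an independent step-by-step NumPy oracle
        on 4 fixed sequences."""
        cfg = tiny_agent_config()
        agent = SACAgent(cfg, seed=5)
        rng = np.random.default_rng(9)
        batch = random_batch(rng, b=4, t=3, obs_dim=cfg.obs_dim)
        eps = rng.standard_normal((4, 3))

        got = agent.bellman_targets(batch, next_eps=eps)

        # --- oracle: plain loops, no shared code path ---
        def gru_forward(cells, seq):
            hs = [np.zeros(cfg.hidden_units) for _ in cells]
            outs = []
            for x in seq:
                inp = x
                for j, cell in enumerate(cells):
                    sig = lambda v: 1 / (1 + np.exp(-v))
                    z = sig(inp @ cell.Wz.data + hs[j] @ cell.Uz.data + cell.bz.data)
                    r = sig(inp @ cell.Wr.data + hs[j] @ cell.Ur.data + cell.br.data)
                    n = np.tanh(inp @ cell.Wn.data + r * (hs[j] @ cell.Un.data) + cell.bn.data)
                    hs[j] = (1 - z) * n + z * hs[j]
                    inp = hs[j]
                outs.append(inp.copy())
            return outs

        expected = np.zeros((4, 3))
        for b in range(4):
            feats = gru_forward(agent.actor.gru.cells, batch["obs"][b])
            for t in range(3):
                f = feats[t + 1]
                hid = np.maximum(f @ agent.actor.fc.W.data + agent.actor.fc.b.data, 0)
                mu = (hid @ agent.actor.mean.W.data + agent.actor.mean.b.data).item()
                raw = (hid @ agent.actor.log_std.W.data + agent.actor.log_std.b.data).item()
                ls = -5.0 + 0.5 * 7.0 * (np.tanh(raw) + 1.0)
                u = mu + math.exp(ls) * eps[b, t]
                a01 = 0.5 * (math.tanh(u) + 1.0)
                logn = (-0.5 * ((u - mu) / math.exp(ls)) ** 2 - ls
                        - 0.5 * math.log(2 * math.pi))
                logjac = (2 * (math.log(2) - u - math.log1p(math.exp(-2 * u)))
                          - math.log(2))
                logpi = logn - logjac
                qs = []
                for tgt in (agent.target1, agent.target2):
                    tf = gru_forward(tgt.gru.cells, batch["obs"][b])[t + 1]
                    x = np.concatenate([tf, [a01]])
                    h1 = np.maximum(x @ tgt.q1.W.data + tgt.q1.b.data, 0)
                    qs.append((h1 @ tgt.q2.W.data + tgt.q2.b.data).item())
                expected[b, t] = batch["rew"][b, t] + cfg.discount * (
                    1 - batch["done"][b, t]) * (min(qs) - agent.alpha * logpi)

        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestLearningHarnesses:
    def test_bandit_mode_converges_to_optimum(self):
        """Single-state bandit, r = -(a - a*)^2, temperature -> 0: the policy
        mode lands within 5% of the closed-form optimum."""
        a_star = 0.7
        cfg = tiny_agent_config(obs_dim=5, hidden_units=16, fc_units=16,
                                batch_size=64, sequence_length=1, burn_in=0,
                                entropy_temperature=1e-4, auto_entropy=False,
                                actor_lr=3e-3, critic_lr=3e-3)
        agent = SACAgent(cfg, seed=0)
        rng = np.random.default_rng(1)
        obs = np.zeros(5)
        for a in rng.uniform(0, 1, 600):
            agent.buffer.add_segment(np.stack([obs, obs]), np.array([a]),
                                     np.array([-(a - a_star) ** 2]), np.array([1.0]))
        for _ in range(1200):
            agent.update(agent.buffer.sample(64, 1, agent._train_rng))
        feat, _ = agent.actor.gru.step_np(obs[None, :],
                                          [np.zeros((1, 16))])
        mu, _ = agent.actor.heads_np(feat)
        mode = 0.5 * (np.tanh(mu.item()) + 1.0)
        assert abs(mode - a_star) <= 0.05 * a_star

    def test_train_local_bookkeeping(self):
        env = ToyDriftEnv(episode_len=40)
        agent = SACAgent(tiny_agent_config(min_buffer=10 ** 9), seed=1)
        agent, log = train_local(agent, env, epochs=1, steps_per_epoch=10)
        assert len(log) == 1
        assert agent.buffer.total == 10
        assert agent.transitions_collected == 10

    def test_train_local_improves_toy_setpoint(self):
        env = ToyDriftEnv()
        cfg = tiny_agent_config(hidden_units=16, fc_units=16, batch_size=32,
                                sequence_length=4, burn_in=0, min_buffer=200,
                                auto_entropy=True, entropy_temperature=0.05,
                                updates_per_epoch=40)
        agent = SACAgent(cfg, seed=2)
        initial = mc_return(agent, ToyDriftEnv(noise=0.0))
        agent, _ = train_local(agent, env, epochs=10, steps_per_epoch=500)
        final = mc_return(agent, ToyDriftEnv(noise=0.0))
        assert final >= initial

    def test_train_local_deterministic_same_seed(self):
        logs = []
        for _ in range(2):
            agent = SACAgent(tiny_agent_config(min_buffer=64, updates_per_epoch=5), seed=7)
            agent, log = train_local(agent, ToyDriftEnv(), epochs=3, steps_per_epoch=80)
            logs.append(log)
        assert repr(logs[0]) == repr(logs[1])


class TestLogProbImplementation:
    def test_density_integrates_to_one(self):
        """The squashed-Gaussian log-density over the [0,1] action integrates
        to ~1 (change-of-variables correctness)."""
        mu, ls = 0.4, -0.7
        a = np.linspace(1e-4, 1 - 1e-4, 20_000)
        u = np.arctanh(2 * a - 1)
        logp = _squash_logprob_np(u, mu, ls)
        assert np.trapezoid(np.exp(logp), a) == pytest.approx(1.0, abs=1e-3)
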