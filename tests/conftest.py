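import numpy as np
import pytest
from hypothesis import settings

from glucofed.agent import AgentConfig, SACAgent
from glucofed.envs import GlucoseEnv
from glucofed.patient_sim import make_cohort, make_scenario

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def adult():
    return make_cohort("adult", 1, seed=7)[0]


@pytest.fixture(scope="session")
def child():
    return make_cohort("child", 1, seed=7)[0]


@pytest.fixture
def adult_env(adult):
    scenario = make_scenario(1, 3, seed=11)
    return GlucoseEnv(adult, scenario, days=1)


@pytest.fixture
def quiet_env(adult):
    """No meals, no CGM noise or lag, no start jitter: pure dynamics."""
    return GlucoseEnv(adult, [], days=1, cgm_noise_sd=0.0, cgm_lag_min=0.0,
                      init_glucose_jitter=0.0)


def tiny_agent_config(**overrides) -> AgentConfig:
    base = dict(obs_dim=5, gru_layers=1, hidden_units=12, fc_units=12,
                batch_size=8, sequence_length=4, burn_in=1, discount=0.9,
                entropy_temperature=0.05, auto_entropy=False, dropout_rate=0.0,
                actor_lr=1e-3, critic_lr=1e-3, min_buffer=32,
                replay_capacity=5000, action_scale=1.0)
    base.update(overrides)
    return AgentConfig(**base)


@pytest.fixture
def tiny_agent():
    return SACAgent(tiny_agent_config(), seed=0)


def random_batch(rng, b=4, t=3, obs_dim=5):
    return {
        "obs": rng.standard_normal((b, t + 1, obs_dim)),
        "act": rng.uniform(0, 1, (b, t)),
        "rew": rng.uniform(-2, 0, (b, t)),
        "done": (rng.random((b, t)) < 0.2).astype(float),
    }
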