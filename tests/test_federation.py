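"""Federated averaging: plans, aggregation, broadcast, privacy, determinism."""

import numpy as np
import pytest

from glucofed.agent import SACAgent, PolicyParams
from glucofed.envs import EpisodeTrace, GlucoseEnv
from glucofed.exceptions import ConfigError, ValidationError
from glucofed.federation import (AggregationPlan, FedClient, ModelUpdate,
                                 RoundConfig, ServerState, aggregate,
                                 make_plan, package_update, run_round)
from glucofed.patient_sim import make_cohort, make_scenario
from glucofed.reward import RISK_ROOT

from conftest import tiny_agent_config


def fake_update(client_id, vec, n=1, risk=0.0):
    params = PolicyParams(vector=np.asarray(vec, dtype=float),
                          index=(("all", (len(vec),), 0),))
    return ModelUpdate(client_id=client_id, params=params, num_samples=n,
                       mean_risk=risk)


def trace_with_bg(values):
    trace = EpisodeTrace()
    for i, g in enumerate(values):
        trace.t_min.append(5.0 * i)
        trace.plasma_glucose.append(g)
    return trace


class TestPackageUpdate:
    def test_untrained_empty_eval_conventions(self, tiny_agent):
        update = package_update(tiny_agent, EpisodeTrace(), "c0")
        assert update.num_samples == 0
        assert update.mean_risk == 0.0

    def test_mean_risk_zero_at_risk_root(self, tiny_agent):
        update = package_update(tiny_agent, trace_with_bg([RISK_ROOT] * 20), "c0")
        assert update.mean_risk == pytest.approx(0.0, abs=1e-12)

    def test_package_roundtrip_identity(self, tiny_agent):
        u1 = package_update(tiny_agent, EpisodeTrace(), "c0")
        tiny_agent.set_params(u1.params)
        u2 = package_update(tiny_agent, EpisodeTrace(), "c0")
        np.testing.assert_array_equal(u1.params.vector, u2.params.vector)

    def test_refuses_nonfinite_params(self, tiny_agent):
        tiny_agent.log_alpha.data = np.array(np.nan)
        with pytest.raises(ValidationError):
            package_update(tiny_agent, EpisodeTrace(), "c0")

    def test_privacy_canary_no_trace_bytes_in_update(self, tiny_agent):
        """Sentinel CGM values planted in the evaluation trace must not
        appear anywhere in the serialized model update."""
        sentinels = [271.828459, 314.159265, 161.803398]
        trace = trace_with_bg(sentinels * 10)
        update = package_update(tiny_agent, trace, "canary")
        blob = update.to_bytes()
        for s in sentinels:
            assert str(s).encode() not in blob
            assert f"{s:.4f}".encode() not in blob


class TestMakePlan:
    def test_uniform_three_clients(self):
        plan = make_plan([fake_update(f"c{i}", [0.0]) for i in range(3)], "uniform")
        np.testing.assert_allclose(plan.weights, [1 / 3] * 3)

    def test_by_samples_proportional(self):
        plan = make_plan([fake_update("a", [0.0], n=2), fake_update("b", [0.0], n=1)],
                         "by_samples")
        np.testing.assert_allclose(plan.weights, [2 / 3, 1 / 3])

    def test_risk_adjusted_handcomputed(self):
        updates = [fake_update("a", [0.0], n=1, risk=0.0),
                   fake_update("b", [0.0], n=1, risk=10.0)]
        plan = make_plan(updates, "risk_adjusted", lambda_risk=1.0)
        np.testing.assert_allclose(plan.weights, [1 / 3, 2 / 3])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        updates = [fake_update(f"c{i}", [0.0], n=int(rng.integers(1, 100)),
                               risk=float(rng.uniform(0, 30))) for i in range(7)]
        for strategy in ("uniform", "by_samples", "risk_adjusted"):
            w = make_plan(updates, strategy).weights
            assert abs(w.sum() - 1.0) < 1e-12 and np.all(w >= 0)

    def test_equal_risks_fall_back_to_samples(self):
        updates = [fake_update("a", [0.0], n=3, risk=5.0),
                   fake_update("b", [0.0], n=1, risk=5.0)]
        plan = make_plan(updates, "risk_adjusted", lambda_risk=2.0)
        np.testing.assert_allclose(plan.weights, [0.75, 0.25])

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValidationError):
            make_plan([], "uniform")
        with pytest.raises(ConfigError):
            make_plan([fake_update("a", [0.0])], "median")

    def test_invalid_plan_weights_rejected(self):
        with pytest.raises(ValidationError):
            AggregationPlan(np.array([0.5, 0.6]))


class TestAggregate:
    def test_single_client_identity(self):
        u = fake_update("a", [1.0, -2.0, 3.0])
        out = aggregate([u], AggregationPlan(np.array([1.0])))
        np.testing.assert_array_equal(out.vector, u.params.vector)

    def test_two_client_mean(self):
        out = aggregate([fake_update("a", [0.0, 2.0]), fake_update("b", [2.0, 4.0])],
                        AggregationPlan(np.array([0.5, 0.5])))
        np.testing.assert_allclose(out.vector, [1.0, 3.0])

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(1)
        vecs = rng.standard_normal((5, 40))
        w = rng.dirichlet(np.ones(5))
        updates = [fake_update(f"c{i}", vecs[i]) for i in range(5)]
        out = aggregate(updates, AggregationPlan(w))
        brute = np.zeros(40)
        for i in range(5):
            for j in range(40):
                brute[j] += w[i] * vecs[i][j]
        np.testing.assert_allclose(out.vector, brute, atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        vecs = rng.standard_normal((4, 10))
        w = rng.dirichlet(np.ones(4))
        updates = [fake_update(f"c{i}", vecs[i]) for i in range(4)]
        a = aggregate(updates, AggregationPlan(w))
        perm = [2, 0, 3, 1]
        b = aggregate([updates[i] for i in perm], AggregationPlan(w[perm]))
        np.testing.assert_allclose(a.vector, b.vector, atol=1e-15)

    def test_identical_vectors_fixed_point(self):
        vec = np.arange(6.0)
        updates = [fake_update(f"c{i}", vec) for i in range(3)]
        out = aggregate(updates, AggregationPlan(np.array([0.2, 0.5, 0.3])))
        np.testing.assert_allclose(out.vector, vec)

    def test_shape_mismatch_names_client(self):
        updates = [fake_update("good", [1.0, 2.0]), fake_update("bad", [1.0])]
        with pytest.raises(ValidationError, match="bad"):
            aggregate(updates, AggregationPlan(np.array([0.5, 0.5])))


def make_clients(n, seed0=0, days=1):
    patients = make_cohort("adult", n, seed=seed0)
    clients = []
    for i, p in enumerate(patients):
        scenario = make_scenario(days, 2, seed=seed0 + 10 + i)
        env = GlucoseEnv(p, scenario, days=days, k_history=1)
        cfg = tiny_agent_config(min_buffer=32, updates_per_epoch=3,
                                action_scale=env.max_rate)
        clients.append(FedClient(p.patient_id, SACAgent(cfg, seed=seed0 + i), env,
                                 val_env=GlucoseEnv(p, scenario, days=days, k_history=1)))
    return clients


class TestRunRound:
    def test_single_client_no_training_keeps_params(self):
        clients = make_clients(1)
        initial = clients[0].agent.get_params().vector.copy()
        rc = RoundConfig(local_epochs=1, steps_per_epoch=0, updates_per_epoch=0)
        server, rows = run_round(clients, ServerState(), rc)
        np.testing.assert_array_equal(server.global_params.vector, initial)

    def test_broadcast_makes_all_clients_identical(self):
        clients = make_clients(3)
        rc = RoundConfig(local_epochs=1, steps_per_epoch=40, updates_per_epoch=2)
        server, rows = run_round(clients, ServerState(), rc)
        for c in clients:
            np.testing.assert_array_equal(c.agent.get_params().vector,
                                          server.global_params.vector)

    def test_failing_client_excluded_not_fatal(self):
        clients = make_clients(2)
        clients[1].env = None  # this client will raise in train_local
        rc = RoundConfig(local_epochs=1, steps_per_epoch=10, updates_per_epoch=0)
        server, rows = run_round(clients, ServerState(), rc)
        failed = [r for r in rows if r.get("failed")]
        assert len(failed) == 1 and failed[0]["client"] == clients[1].client_id
        assert server.global_params is not None

    def test_two_rounds_deterministic_with_same_seeds(self):
        logs = []
        for _ in range(2):
            clients = make_clients(2, seed0=3)
            server = ServerState()
            rc = RoundConfig(local_epochs=1, steps_per_epoch=60, updates_per_epoch=2)
            rows_all = []
            for _ in range(2):
                server, rows = run_round(clients, server, rc)
                rows_all.append(rows)
            logs.append((server.global_params.vector.copy(), repr(rows_all)))
        np.testing.assert_array_equal(logs[0][0], logs[1][0])
        assert logs[0][1] == logs[1][1]
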