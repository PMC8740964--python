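"""Cascade engine: message propagation, timestep loop, replicate batches."""

import networkx as nx
import numpy as np
import pytest

from podsim import (
    ContagionSpec,
    GraphSpec,
    Message,
    SimulationConfig,
    SocialGraph,
    make_fixture,
    preset,
    propagate_message,
    run_batch,
    run_simulation,
)
from podsim.analysis import path_probability
from podsim.engine import OUTCOME_BELIEVED, OUTCOME_DUPLICATE


def small_config(**kwargs):
    defaults = dict(n_agents=60, horizon=10, replicates=2,
                    graph_spec=GraphSpec(family="ER", er_rho=0.15))
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestPropagateMessage:
    def test_certain_adoption_percolates_connected_graph(self, rng):
        sg = SocialGraph(nx.cycle_graph(12))
        sg.set_beliefs([0, 1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1])
        spec = ContagionSpec(variant="simple", p=1.0)
        msg = Message(uid=1, content=6, origin="i1", emitted_at=1)
        propagate_message(sg, msg, seeds=[6], spec=spec, rng=rng)
        assert np.all(sg.beliefs == 6)

    def test_zero_probability_changes_nothing(self, rng):
        sg = SocialGraph(nx.complete_graph(8))
        before = [0, 1, 2, 3, 4, 5, 6, 0]
        sg.set_beliefs(before)
        msg = Message(uid=1, content=6, origin="i1", emitted_at=1)
        propagate_message(sg, msg, seeds=list(range(8)),
                          spec=ContagionSpec(variant="simple", p=0.0), rng=rng)
        assert list(sg.beliefs) == before

    def test_believe_once_single_share(self, rng):
        """An agent reached twice after believing shares exactly once."""
        sg = SocialGraph(nx.complete_graph(6))
        sg.set_beliefs([6] * 6)
        msg = Message(uid=9, content=6, origin="i1", emitted_at=1)
        events = propagate_message(sg, msg, seeds=[0], spec=preset("dcc"), rng=rng)
        believed = events[events.outcome == OUTCOME_BELIEVED]
        assert believed.receiver.is_unique
        # dense graph: later copies of the uid are ignored, not re-tried
        assert (events.outcome == OUTCOME_DUPLICATE).any()

    def test_chain_transmission_matches_path_probability(self):
        """Monte-Carlo frequency of the message clearing two hops equals the
        product of per-hop sigmoid probabilities."""
        spec = preset("dcc")
        target_hits = 0
        n = 1500
        rng = np.random.default_rng(99)
        for trial in range(n):
            fresh, inst = make_fixture("line-chain")
            msg = Message(uid=trial, content=6, origin="i1", emitted_at=1)
            propagate_message(fresh, msg, seeds=sorted(inst.subscribers), spec=spec, rng=rng)
            if fresh.beliefs[2] == 6:  # agent two hops in (initial belief 4)
                target_hits += 1
        expected = path_probability(spec, [6, 5, 4], 6)  # ~0.9997*0.982*0.5
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert target_hits / n == pytest.approx(expected, abs=3.5 * sigma)

    def test_trial_mode_once_caps_trials_per_uid(self, rng):
        """With many believing neighbors an agent still gets one trial per message."""
        g = nx.star_graph(10)  # hub 0, leaves 1..10
        sg = SocialGraph(g)
        sg.set_beliefs([4] + [6] * 10)
        # deliver to all leaves; every leaf believes (distance 0) and shares to hub
        msg = Message(uid=1, content=6, origin="i1", emitted_at=1)
        events = propagate_message(sg, msg, seeds=list(range(1, 11)),
                                   spec=preset("dcc"), rng=np.random.default_rng(0))
        hub_events = events[events.receiver == 0]
        trials = hub_events[hub_events.outcome != OUTCOME_DUPLICATE]
        assert len(trials) == 1
        assert len(hub_events) == 10

    def test_per_delivery_mode_retries_until_belief(self):
        g = nx.star_graph(10)
        sg = SocialGraph(g)
        sg.set_beliefs([4] + [6] * 10)
        msg = Message(uid=1, content=6, origin="i1", emitted_at=1)
        events = propagate_message(sg, msg, seeds=list(range(1, 11)),
                                   spec=preset("dcc"), rng=np.random.default_rng(0),
                                   trial_mode="per-delivery")
        hub_events = events[events.receiver == 0]
        trials = hub_events[hub_events.outcome != OUTCOME_DUPLICATE]
        assert len(trials) >= 1
        believed = hub_events[hub_events.outcome == OUTCOME_BELIEVED]
        assert len(believed) <= 1


class TestStepAndRun:
    def test_no_institutions_histogram_constant(self):
        cfg = small_config(n_institutions=0)
        result = run_simulation(cfg, seed=4)
        assert np.array_equal(result.timeseries.counts,
                              np.tile(result.timeseries.counts[0], (11, 1)))

    def test_empty_subscribers_histogram_constant(self):
        """An institution nobody subscribes to leaves the system closed."""
        from podsim import Institution, build_single_schedule, wire_subscribers
        from podsim.engine import step as engine_step

        sg = SocialGraph(nx.complete_graph(10))
        sg.set_beliefs([0] * 10)  # nobody within epsilon=0 of belief 6
        inst = wire_subscribers(
            sg, Institution(id="i1", belief=6, schedule=build_single_schedule(5, 6)),
            epsilon=0,
        )
        before = sg.beliefs.copy()
        for t in range(1, 6):
            engine_step(sg, [inst], t, preset("dcc"), np.random.default_rng(1))
        assert np.array_equal(sg.beliefs, before)

    def test_conservation_every_timestep(self):
        for method in ("simple", "proportional", "dcc"):
            cfg = small_config(contagion_spec=preset(method))
            result = run_simulation(cfg, seed=11)
            assert np.all(result.timeseries.counts.sum(axis=1) == cfg.n_agents)

    def test_t0_row_is_initial_assignment(self):
        cfg = small_config()
        result = run_simulation(cfg, seed=2)
        assert result.timeseries.counts[0].sum() == 60

    def test_determinism_same_seed(self):
        cfg = small_config(event_log=True)
        a = run_simulation(cfg, seed=42)
        b = run_simulation(cfg, seed=42)
        assert np.array_equal(a.timeseries.counts, b.timeseries.counts)
        assert a.events.equals(b.events)
        assert np.array_equal(a.final_beliefs, b.final_beliefs)

    def test_ledger_integrity_believed_once(self):
        """No (agent, uid) pair ever records two believed outcomes."""
        cfg = small_config(event_log=True, contagion_spec=preset("simple"))
        result = run_simulation(cfg, seed=13)
        believed = result.events[result.events.outcome == OUTCOME_BELIEVED]
        assert not believed.duplicated(subset=["message_uid", "receiver"]).any()

    def test_shares_only_after_believing(self):
        """Every agent-sender of a delivery believed that uid beforehand, so
        shared content always equals the sharer's belief at share time."""
        cfg = small_config(event_log=True)
        result = run_simulation(cfg, seed=21)
        ev = result.events.reset_index(drop=True)
        believed_pairs = set(
            zip(ev.loc[ev.outcome == OUTCOME_BELIEVED, "message_uid"],
                ev.loc[ev.outcome == OUTCOME_BELIEVED, "receiver"])
        )
        agent_sends = ev[ev.sender >= 0]
        assert all(
            (uid, s) in believed_pairs
            for uid, s in zip(agent_sends.message_uid, agent_sends.sender)
        )

    def test_uids_distinct_across_run(self):
        cfg = small_config(event_log=True, n_institutions=2)
        result = run_simulation(cfg, seed=5)
        ev = result.events
        # each (t, institution-origin) broadcast has its own uid: uids seen at
        # two different timesteps would violate uniqueness
        t_per_uid = ev.groupby("message_uid")["t"].nunique()
        assert (t_per_uid == 1).all()
        assert ev.message_uid.nunique() == 10 * 2  # T * institutions

    def test_proportional_er_initial_distribution_frozen(self):
        cfg = small_config(contagion_spec=preset("proportional"), n_agents=120)
        result = run_simulation(cfg, seed=17)
        assert np.array_equal(result.timeseries.counts[0], result.timeseries.counts[-1])


class TestRunBatch:
    def test_single_replicate_mean_is_run_variance_zero(self):
        cfg = small_config()
        batch = run_batch(cfg, replicates=1, base_seed=7)
        assert np.array_equal(batch.mean_fractions, batch.results[0].timeseries.fractions)
        assert np.all(batch.var_fractions == 0)

    def test_replicates_use_consecutive_seeds(self):
        cfg = small_config()
        batch = run_batch(cfg, replicates=3, base_seed=50)
        assert [r.seed for r in batch.results] == [50, 51, 52]
        solo = run_simulation(cfg, seed=51)
        assert np.array_equal(batch.results[1].timeseries.counts, solo.timeseries.counts)

    def test_extending_batch_preserves_existing_runs(self):
        cfg = small_config()
        short = run_batch(cfg, replicates=2, base_seed=30)
        longer = run_batch(cfg, replicates=4, base_seed=30)
        for a, b in zip(short.results, longer.results):
            assert np.array_equal(a.timeseries.counts, b.timeseries.counts)
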