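"""Environment generation, agent rollouts, occupancy and mood comparison."""

import dataclasses

import numpy as np
import pytest

from moodpomdp.graph import GraphEdge, GraphNode, PolicyGraph
from moodpomdp.sim import (
    EnvironmentConfig,
    belief_occupancy,
    estimate_discounted_return,
    generate_environment,
    graph_stationary_occupancy,
    mood_comparison_report,
    run_agent,
    solve_mood,
)

from conftest import random_pomdp
from test_policy_graph import make_graph


class TestEnvironment:
    def test_absorbing_chain_stays_put(self):
        cfg = EnvironmentConfig(n_steps=50, stay_probability=1.0, seed=1,
                                start_state="stressful")
        states = generate_environment(cfg)
        assert np.all(states == 0)

    def test_seed_determinism(self):
        cfg = EnvironmentConfig(n_steps=200, stay_probability=0.8, seed=42)
        assert np.array_equal(generate_environment(cfg), generate_environment(cfg))
        other = dataclasses.replace(cfg, seed=43)
        assert not np.array_equal(generate_environment(cfg), generate_environment(other))

    def test_switch_frequency_binomial(self):
        n = 10_000
        stay = 0.9
        cfg = EnvironmentConfig(n_steps=n, stay_probability=stay, seed=7)
        states = generate_environment(cfg)
        switches = np.mean(states[1:] != states[:-1])
        se = np.sqrt(stay * (1 - stay) / (n - 1))
        assert abs(switches - (1 - stay)) < 3 * se

    def test_schedule_override(self):
        cfg = EnvironmentConfig(n_steps=3, schedule=["stressful", "not_stressful",
                                                     "stressful"])
        assert generate_environment(cfg).tolist() == [0, 1, 0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentConfig(n_steps=0)
        with pytest.raises(ValueError):
            EnvironmentConfig(n_steps=1, stay_probability=1.5)


class TestRunAgent:
    def test_deterministic_model_deterministic_trajectory(self):
        m = random_pomdp(np.random.default_rng(0), n_actions=1)
        m = dataclasses.replace(m, transition=np.eye(2)[None], likelihood=np.eye(2)[None])
        cfg = EnvironmentConfig(n_steps=20, schedule=[0] * 21, seed=3)
        t1 = run_agent(m, lambda b: "a0", cfg, b0=[1.0, 0.0])
        t2 = run_agent(m, lambda b: "a0", cfg, b0=[1.0, 0.0])
        assert np.array_equal(t1.observations, t2.observations)
        assert np.all(t1.observations == 0)
        assert np.allclose(t1.beliefs[:, 0], 1.0)

    def test_seeded_reproducibility(self, solved_moods):
        model, _, policy, _ = solved_moods["healthy"]
        cfg = EnvironmentConfig(n_steps=100, seed=11)
        t1 = run_agent(model, policy, cfg)
        t2 = run_agent(model, policy, cfg)
        assert np.array_equal(t1.states, t2.states)
        assert np.array_equal(t1.actions, t2.actions)
        assert np.allclose(t1.beliefs, t2.beliefs)

    def test_depression_stress_is_permanent(self, solved_moods):
        """Ten stressful steps followed by unbroken calm: the depressed
        agent's stress expectation never recovers below one half."""
        model, _, policy, _ = solved_moods["depression"]
        schedule = ["stressful"] * 10 + ["not_stressful"] * 91
        cfg = EnvironmentConfig(n_steps=100, schedule=schedule, seed=5)
        traj = run_agent(model, policy, cfg)
        assert np.all(traj.p_stress[10:] > 0.5)

    def test_rewards_are_reward_matrix_entries(self, solved_moods):
        model, _, policy, _ = solved_moods["healthy"]
        cfg = EnvironmentConfig(n_steps=50, seed=9)
        traj = run_agent(model, policy, cfg)
        expected = model.reward[traj.actions, traj.states]
        assert np.array_equal(traj.rewards, expected)

    def test_trajectory_frame(self, solved_moods):
        model, _, policy, _ = solved_moods["healthy"]
        cfg = EnvironmentConfig(n_steps=10, seed=9)
        df = run_agent(model, policy, cfg).to_frame(model)
        assert len(df) == 10
        assert set(df.action).issubset(set(model.action_labels))


class TestBeliefOccupancy:
    def test_constant_trajectory_single_bin(self, solved_moods):
        model, _, policy, _ = solved_moods["healthy"]
        cfg = EnvironmentConfig(n_steps=30, seed=2)
        traj = run_agent(model, policy, cfg)
        traj.beliefs[:] = np.array([0.42, 0.58])
        occ = belief_occupancy(traj, n_bins=10, burn_in=5)
        assert occ.histogram.sum() == pytest.approx(1.0)
        assert np.count_nonzero(occ.histogram) == 1
        assert occ.mean_stress_probability == pytest.approx(0.42)

    def test_depression_density_skewed_right(self, solved_moods):
        model, _, policy, _ = solved_moods["depression"]
        cfg = EnvironmentConfig(n_steps=4000, stay_probability=0.5, seed=13)
        traj = run_agent(model, policy, cfg)
        occ = belief_occupancy(traj, n_bins=20, burn_in=500)
        above = occ.histogram[10:].sum()
        assert above > occ.histogram[:10].sum()
        assert occ.mean_stress_probability > 0.5

    def test_degenerate_inputs_rejected(self, solved_moods):
        model, _, policy, _ = solved_moods["healthy"]
        traj = run_agent(model, policy, EnvironmentConfig(n_steps=10, seed=1))
        with pytest.raises(ValueError):
            belief_occupancy(traj, n_bins=1, burn_in=0)
        with pytest.raises(ValueError):
            belief_occupancy(traj, n_bins=5, burn_in=10)


class TestStationaryOccupancy:
    def test_single_self_loop(self):
        g = make_graph([(0, 0, "o", 1.0)], 1)
        occ = graph_stationary_occupancy(g)
        assert occ.probs.tolist() == [1.0]

    def test_symmetric_two_cycle(self):
        g = make_graph([(0, 1, "o", 1.0), (1, 0, "o", 1.0)], 2)
        occ = graph_stationary_occupancy(g)
        assert np.allclose(occ.probs, [0.5, 0.5], atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_linear_solve_oracle(self, seed):
        """Power iteration agrees with direct solution of pi P = pi on
        strongly connected random chains."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        P = rng.dirichlet(np.ones(n), size=n)
        edges = [(u, v, f"o{v}", P[u, v]) for u in range(n) for v in range(n)]
        g = make_graph(edges, n)
        occ = graph_stationary_occupancy(g)
        A = np.vstack([P.T - np.eye(n), np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi = np.linalg.lstsq(A, b, rcond=None)[0]
        assert np.allclose(occ.probs, pi, atol=1e-9)

    def test_absorption_weights_split_between_traps(self):
        # start node feeds two absorbing sinks 30/70
        g = make_graph(
            [(0, 1, "o", 0.3), (0, 2, "o2", 0.7),
             (1, 1, "o", 1.0), (2, 2, "o", 1.0)], 3
        )
        occ = graph_stationary_occupancy(g)
        assert np.allclose(occ.probs, [0.0, 0.3, 0.7], atol=1e-12)
        reaches = {min(c.nodes): c.reach_probability for c in occ.components}
        assert reaches == {1: pytest.approx(0.3), 2: pytest.approx(0.7)}

    def test_empirical_occupancy_matches_chain(self, solved_moods):
        """Long-run belief statistics track the policy-graph chain when the
        environment follows the model's own transition kernel."""
        model, _, policy, graph = solved_moods["depression"]
        occ = graph_stationary_occupancy(graph)
        # environment schedule drawn from the model's own (asymmetric) kernel
        rng = np.random.default_rng(21)
        stay = {0: model.transition[0, 0, 0], 1: model.transition[0, 1, 1]}
        s, schedule = 0, []
        for _ in range(20_001):
            schedule.append(s)
            if rng.random() >= stay[s]:
                s = 1 - s
        cfg = EnvironmentConfig(n_steps=20_000, schedule=schedule, seed=21)
        traj = run_agent(model, policy, cfg)
        emp_mean = traj.p_stress[2000:].mean()
        assert abs(emp_mean - occ.p_stress_mean(graph)) < 0.05

        # anxiety: all stationary mass sits on the single trap node, so the
        # empirical belief must settle within merge tolerance of it
        modelx, _, policyx, graphx = solved_moods["anxiety"]
        occx = graph_stationary_occupancy(graphx)
        trap_id = int(np.argmax(occx.probs))
        trap_p = {n.id: n.p_stress for n in graphx.nodes}[trap_id]
        cfgx = EnvironmentConfig(n_steps=4000, stay_probability=0.8, seed=22)
        trajx = run_agent(modelx, policyx, cfgx)
        frac_near = np.mean(np.abs(trajx.p_stress[500:] - trap_p)
                            <= 3 * graphx.merge_tol)
        assert occx.probs[trap_id] == pytest.approx(1.0)
        assert frac_near > 0.95
        assert np.all((trajx.p_stress[500:] > 0.35) & (trajx.p_stress[500:] < 0.65))

    def test_mirror_occupancy(self, solved_moods):
        _, _, _, gd = solved_moods["depression"]
        _, _, _, gm = solved_moods["mania"]
        od = graph_stationary_occupancy(gd)
        om = graph_stationary_occupancy(gm)
        d = sorted(zip((n.p_stress for n in gd.nodes), od.probs))
        m = sorted(zip((1 - n.p_stress for n in gm.nodes), om.probs))
        assert np.allclose([x[0] for x in d], [x[0] for x in m], atol=1e-9)
        assert np.allclose([x[1] for x in d], [x[1] for x in m], atol=1e-9)


class TestMonteCarlo:
    def test_return_close_to_value_function(self, solved_moods):
        model, V, policy, graph = solved_moods["depression"]
        mc, se, returns = estimate_discounted_return(
            model, policy, graph.b0, n_episodes=300, n_steps=250, seed=3
        )
        assert len(returns) == 300
        assert se < 0.05
        assert abs(mc - V.value(graph.b0)) < 0.1

    def test_seed_reproducibility(self, solved_moods):
        model, _, policy, graph = solved_moods["healthy"]
        a = estimate_discounted_return(model, policy, graph.b0, 50, 50, seed=4)[0]
        b = estimate_discounted_return(model, policy, graph.b0, 50, 50, seed=4)[0]
        assert a == b


class TestComparisonReport:
    def test_identical_model_gives_identical_rows(self, healthy):
        s1 = solve_mood(healthy)
        s2 = solve_mood(healthy)
        df = mood_comparison_report([s1, s2])
        assert df.iloc[0].drop("mood").equals(df.iloc[1].drop("mood"))

    def test_mismatched_settings_rejected(self, healthy, anxiety):
        s1 = solve_mood(healthy, resolution=20)
        s2 = solve_mood(anxiety, resolution=10)
        with pytest.raises(ValueError, match="mismatched"):
            mood_comparison_report([s1, s2])

    def test_report_columns(self, solved_moods):
        from moodpomdp.sim import SolvedMood

        solved = [
            SolvedMood(name, model, V, policy, graph)
            for name, (model, V, policy, graph) in solved_moods.items()
        ]
        df = mood_comparison_report(solved)
        assert set(df.mood) == {"healthy", "depression", "mania", "anxiety"}
        assert {"mean_stress_probability", "mean_stress_unweighted",
                "total_expected_reward", "n_nodes"} <= set(df.columns)
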