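"""Unit and property tests for the simulation engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boldsim import (ConfigurationError, SimulationConfig, SimulationError,
                     decide_and_move, init_group, run_simulation, step,
                     update_probability)
from boldsim.engine import (AgentState, _shuffle_in_place,
                            social_action_central, social_action_majority,
                            social_action_nearest)


def make_group(positions, rule="central", seed=0, **kwargs):
    cfg = SimulationConfig(n=len(positions), rule=rule, seed=seed,
                           p_baseline=0.5, d_food=kwargs.pop("d_food", 100.0),
                           threshold=kwargs.pop("threshold", 10.0), **kwargs)
    group = init_group(cfg)
    for agent, d in zip(group.agents, positions):
        agent.d = d
    return cfg, group


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,field", [
        (dict(n=0), "n"),
        (dict(n=1, rule="central"), "n"),
        (dict(n=1, rule="majority"), "n"),
        (dict(p_baseline=0.0), "p_baseline"),
        (dict(p_baseline=1.5), "p_baseline"),
        (dict(omega_difference=-1e-4), "omega_difference"),
        (dict(d_food=0.0), "d_food"),
        (dict(threshold=0.0), "threshold"),
        (dict(threshold=100.0, d_food=100.0), "threshold"),
        (dict(rule="telepathy"), "rule"),
        (dict(max_steps=0), "max_steps"),
        (dict(omega_indexing="two_based"), "omega_indexing"),
    ])
    def test_invalid_configs_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(**kwargs)

    def test_singleton_group_allowed_for_non_social(self):
        cfg = SimulationConfig(n=1, rule="non_social", threshold=1, d_food=5)
        assert cfg.n == 1


class TestInitGroup:
    def test_boldness_increments_follow_hierarchy(self):
        group = init_group(SimulationConfig(n=10, omega_difference=0.001))
        assert group.agents[0].omega == 0.0
        assert group.agents[3].omega == pytest.approx(0.003)  # omega_4 = 3*diff
        assert [a.identity for a in group.agents] == list(range(1, 11))

    def test_one_based_indexing_shifts_every_increment(self):
        group = init_group(SimulationConfig(n=10, omega_difference=0.001,
                                            omega_indexing="one_based"))
        assert group.agents[0].omega == pytest.approx(0.001)
        assert group.agents[9].omega == pytest.approx(0.010)

    def test_zero_increment_makes_agents_identical(self):
        group = init_group(SimulationConfig(n=5, omega_difference=0.0))
        assert all(a.omega == 0.0 for a in group.agents)
        assert all(a.p == group.agents[0].p for a in group.agents)

    def test_everyone_starts_home_at_baseline_probability(self):
        cfg = SimulationConfig(n=7, p_baseline=0.25)
        group = init_group(cfg)
        assert all(a.d == 0.0 for a in group.agents)
        assert all(a.p == 0.25 for a in group.agents)

    def test_speeds_are_uniform_on_the_stated_interval(self):
        group = init_group(SimulationConfig(n=50, seed=3))
        speeds = np.array([a.speed for a in group.agents])
        assert np.all((speeds >= 0.95) & (speeds <= 1.0))
        assert len(np.unique(speeds)) == 50

    def test_same_seed_gives_identical_groups(self):
        a = init_group(SimulationConfig(n=10, seed=42))
        b = init_group(SimulationConfig(n=10, seed=42))
        assert [x.speed for x in a.agents] == [x.speed for x in b.agents]


class TestProbabilityUpdate:
    def test_three_updates_accumulate_three_increments(self):
        agent = AgentState(identity=2, speed=1.0, omega=0.001, p=0.001)
        for _ in range(3):
            update_probability(agent)
        assert agent.p == pytest.approx(0.004, abs=1e-15)

    def test_zero_increment_never_changes_p(self):
        agent = AgentState(identity=1, speed=1.0, omega=0.0, p=0.001)
        for _ in range(100):
            update_probability(agent)
        assert agent.p == 0.001

    def test_recursion_matches_closed_form_over_a_thousand_periods(self):
        agent = AgentState(identity=4, speed=1.0, omega=0.003, p=0.001)
        for t in range(1, 1001):
            update_probability(agent)
            assert abs(agent.p - (0.001 + t * 0.003)) < 1e-12

    def test_p_is_not_clamped_at_one(self):
        agent = AgentState(identity=9, speed=1.0, omega=0.5, p=0.9)
        update_probability(agent)
        update_probability(agent)
        assert agent.p == pytest.approx(1.9)


class TestDecideAndMove:
    def test_agent_at_the_foraging_site_is_frozen(self):
        cfg, group = make_group([100.3, 0.0], rule="non_social")
        decide_and_move(group.agents[0], group, cfg)
        assert group.agents[0].d == 100.3

    def test_agent_behind_the_refuge_is_forced_outward(self):
        cfg, group = make_group([-0.5, 0.0], rule="non_social")
        group.agents[0].speed = 0.97
        decide_and_move(group.agents[0], group, cfg)
        assert group.agents[0].d == pytest.approx(0.47)

    def test_certain_probability_always_moves_outward(self):
        cfg, group = make_group([0.0, 0.0], rule="non_social")
        group.agents[0].p = 1.0
        for _ in range(20):
            d_before = group.agents[0].d
            decide_and_move(group.agents[0], group, cfg)
            assert group.agents[0].d == pytest.approx(
                d_before + group.agents[0].speed)


class TestSocialActions:
    def test_central_moves_toward_the_others_mean(self):
        cfg, group = make_group([2.0, 0.0, 10.0])
        group.agents[0].speed = 1.0
        social_action_central(group.agents[0], group)  # d' = 5, outward
        assert group.agents[0].d == pytest.approx(3.0)

    def test_central_no_move_when_exactly_at_centroid(self):
        cfg, group = make_group([5.0, 0.0, 10.0])
        social_action_central(group.agents[0], group)
        assert group.agents[0].d == 5.0

    def test_central_full_step_may_overshoot_the_centroid(self):
        cfg, group = make_group([1.0, 1.2, 1.2])
        group.agents[0].speed = 0.95
        social_action_central(group.agents[0], group)  # d' = 1.2, step 0.95
        assert group.agents[0].d == pytest.approx(1.95)

    def test_nearest_picks_the_closer_neighbour(self):
        cfg, group = make_group([7.5, 5.0, 9.0], rule="nearest_neighbour")
        group.agents[0].speed = 1.0
        social_action_nearest(group.agents[0], group)  # 9.0 at 1.5 < 2.5
        assert group.agents[0].d == pytest.approx(8.5)

    def test_nearest_colocated_neighbour_means_no_move(self):
        cfg, group = make_group([5.0, 5.0, 9.0], rule="nearest_neighbour")
        social_action_nearest(group.agents[0], group)
        assert group.agents[0].d == 5.0

    def test_nearest_tie_is_broken_uniformly(self):
        ups = 0
        trials = 4000
        for seed in range(trials):
            cfg, group = make_group([5.0, 3.0, 7.0], seed=seed,
                                    rule="nearest_neighbour")
            group.agents[0].speed = 1.0
            social_action_nearest(group.agents[0], group)
            ups += group.agents[0].d > 5.0
        se = (trials * 0.25) ** 0.5
        assert abs(ups - trials / 2) < 3 * se

    def test_majority_moves_toward_the_larger_side(self):
        cfg, group = make_group([5.0, 6.0, 7.0, 8.0, 1.0, 2.0], rule="majority")
        group.agents[0].speed = 1.0
        social_action_majority(group.agents[0], group)  # 3 ahead, 2 behind
        assert group.agents[0].d == pytest.approx(6.0)

    def test_majority_tie_means_no_move(self):
        cfg, group = make_group([5.0, 6.0, 1.0], rule="majority")
        social_action_majority(group.agents[0], group)
        assert group.agents[0].d == 5.0

    def test_majority_colocated_colleagues_count_for_neither_side(self):
        cfg, group = make_group([5.0, 5.0, 5.0], rule="majority")
        social_action_majority(group.agents[0], group)
        assert group.agents[0].d == 5.0


class TestStep:
    def test_forced_march_advances_by_speed_each_period(self):
        cfg = SimulationConfig(n=1, rule="non_social", p_baseline=1.0,
                               omega_difference=0.0, d_food=50, threshold=1,
                               seed=5)
        group = init_group(cfg)
        s = group.agents[0].speed
        for k in range(1, 11):
            step(group, cfg)
            assert group.agents[0].d == pytest.approx(k * s)
        assert group.t == 10

    def test_fully_arrived_group_only_advances_the_clock(self):
        cfg, group = make_group([101.0, 102.0, 103.0], rule="central")
        step(group, cfg)
        assert group.t == 1
        assert [a.d for a in group.agents] == [101.0, 102.0, 103.0]

    def test_acting_order_is_shuffled_uniformly(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(10)
        trials = 10_000
        for _ in range(trials):
            order = list(range(10))
            _shuffle_in_place(order, rng)
            counts[order[0]] += 1
        from scipy import stats
        chi2 = ((counts - trials / 10) ** 2 / (trials / 10)).sum()
        assert stats.chi2.sf(chi2, 9) > 0.001


class TestRunSimulation:
    def test_forced_march_end_time_is_the_step_count_to_distance(self):
        cfg = SimulationConfig(n=1, rule="non_social", p_baseline=1.0,
                               omega_difference=0.0, d_food=100, threshold=10,
                               seed=2)
        log = run_simulation(cfg)
        s = log.speeds[0]
        assert log.end_time == int(np.ceil(100.0 / s))

    def test_same_seed_same_config_identical_event_log(self):
        cfg = SimulationConfig(n=6, rule="majority", p_baseline=0.02,
                               d_food=30, seed=99)
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert np.array_equal(a.leave_time, b.leave_time)
        assert np.array_equal(a.arrival_time, b.arrival_time)
        assert np.array_equal(a.speeds, b.speeds)
        assert a.end_time == b.end_time

    def test_max_steps_guard_raises_loudly(self):
        cfg = SimulationConfig(n=2, rule="central", p_baseline=1e-6,
                               d_food=100, seed=0, max_steps=50)
        with pytest.raises(SimulationError, match="max_steps"):
            run_simulation(cfg)

    @pytest.mark.parametrize("rule", ["central", "nearest_neighbour",
                                      "majority", "non_social"])
    @pytest.mark.parametrize("omega_indexing", ["zero_based", "one_based"])
    def test_compiled_kernel_matches_reference_bit_for_bit(self, rule,
                                                           omega_indexing):
        cfg = SimulationConfig(n=6, rule=rule, p_baseline=0.03,
                               omega_difference=0.004, d_food=25, threshold=5,
                               seed=17, omega_indexing=omega_indexing)
        fast = run_simulation(cfg, rng=np.random.default_rng(cfg.seed))
        slow = run_simulation(cfg, rng=np.random.default_rng(cfg.seed),
                              use_kernel=False)
        assert np.array_equal(fast.speeds, slow.speeds)
        assert np.array_equal(fast.leave_time, slow.leave_time)
        assert np.array_equal(fast.arrival_time, slow.arrival_time)
        assert fast.end_time == slow.end_time


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 6),
    p_baseline=st.floats(0.02, 0.5),
    omega_difference=st.floats(0.0, 0.01),
    rule=st.sampled_from(["central", "nearest_neighbour", "majority",
                          "non_social"]),
    seed=st.integers(0, 10_000),
)
def test_trajectory_invariants(n, p_baseline, omega_difference, rule, seed):
    """Displacement quantization, absorption and monotonicity all hold on
    randomly configured short simulations."""
    cfg = SimulationConfig(n=n, p_baseline=p_baseline,
                           omega_difference=omega_difference, rule=rule,
                           d_food=12.0, threshold=3.0, seed=seed,
                           max_steps=200_000)
    log = run_simulation(cfg, record_trajectory=True)
    traj = log.trajectory
    speeds = log.speeds
    moves = np.diff(traj, axis=0)
    # every per-period displacement is 0 or +/- the agent's own speed
    for j in range(n):
        deltas = np.unique(np.abs(moves[:, j]).round(12))
        assert set(deltas).issubset({0.0, round(speeds[j], 12)})
    # absorption: once at the foraging site, the position never changes
    for j in range(n):
        arrived = np.nonzero(traj[:, j] >= cfg.d_food)[0]
        assert len(arrived) > 0
        assert np.all(traj[arrived[0]:, j] == traj[arrived[0], j])
        assert cfg.d_food <= traj[-1, j] < cfg.d_food + 1.0
    if rule == "non_social":
        assert np.all(moves >= 0.0)  # failing the draw means standing still
    log.validate()
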