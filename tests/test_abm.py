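import numpy as np
import pytest

from nestflow import (
    AgentState,
    AgentTraits,
    Condition,
    DirectionRule,
    InitiationRule,
    SimConfig,
    find_neighbours,
    interaction_phase,
    is_active,
    move_agent,
    run_simulation,
)
from nestflow.abm import _advance, _draw_active
from nestflow.traits import build_traits


class TestActivation:
    def test_huge_activity_always_active(self, rng):
        assert all(is_active(1e9, rng) for _ in range(100))

    def test_activation_probability_matches_exponential_cdf(self, rng):
        # P(active | A=1) = 1 - exp(-1)
        freq = _draw_active(np.ones(1_000_000), rng).mean()
        p = 1 - np.exp(-1)
        se = np.sqrt(p * (1 - p) / 1_000_000)
        assert abs(freq - p) < 3 * se

    def test_nonpositive_activity_rejected(self, rng):
        with pytest.raises(Exception):
            is_active(0.0, rng)


class TestMovement:
    def test_zero_turning_walks_a_straight_line(self, rng):
        config = SimConfig(seed=0)
        state = AgentState(x=10.0, y=10.0, heading=90.0, active=True)
        traits = AgentTraits(0, 1.0, 0.0)
        for _ in range(10):
            state = move_agent(state, traits, rng, config)
        assert state.x == pytest.approx(10.0)
        assert state.y == pytest.approx(15.0)  # 10 steps of 0.5 patches north

    def test_inactive_agent_does_not_move(self, rng):
        config = SimConfig(seed=0)
        state = AgentState(x=3.0, y=4.0, heading=10.0, active=False)
        out = move_agent(state, AgentTraits(0, 1.0, 60.0), rng, config)
        assert (out.x, out.y, out.heading) == (3.0, 4.0, 10.0)

    def test_boundary_sets_coordinate_to_wall_and_reflects_heading(self, rng):
        config = SimConfig(seed=0)  # default boundary="reflect"
        state = AgentState(x=49.9, y=25.0, heading=0.0, active=True)
        out = move_agent(state, AgentTraits(0, 1.0, 0.0), rng, config)
        assert out.x == pytest.approx(50.0)
        assert out.heading == pytest.approx(180.0)

    def test_clamp_variant_keeps_heading(self, rng):
        config = SimConfig(seed=0, boundary="clamp")
        state = AgentState(x=49.9, y=25.0, heading=0.0, active=True)
        out = move_agent(state, AgentTraits(0, 1.0, 0.0), rng, config)
        assert out.x == pytest.approx(50.0)
        assert out.heading == pytest.approx(0.0)

    @pytest.mark.parametrize("boundary", ["reflect", "clamp"])
    def test_positions_never_leave_the_nest(self, rng, boundary):
        n, grid = 50, 10.0
        x = rng.uniform(0, grid, n)
        y = rng.uniform(0, grid, n)
        heading = rng.uniform(0, 360, n)
        turning = rng.uniform(0, 120, n)
        for _ in range(500):
            active = rng.random(n) < 0.7
            _advance(x, y, heading, active, turning, 0.5, grid, rng, boundary)
            assert np.all((x >= 0) & (x <= grid) & (y >= 0) & (y <= grid))
            assert np.all((heading >= 0) & (heading < 360))

    def test_straight_walkers_cover_more_patches_than_sinuous_ones(self):
        """Low turning indices mean far-ranging paths: distinct-patch coverage
        decreases from the straightest to the most sinuous quartile."""
        rng = np.random.default_rng(99)
        traits = build_traits(100, 1.0, 60.0, Condition.TI_VARIABLE, rng)
        n, grid = 100, 50.0
        x = rng.uniform(0, grid, n)
        y = rng.uniform(0, grid, n)
        heading = rng.uniform(0, 360, n)
        visited = [set() for _ in range(n)]
        for _ in range(3000):
            active = rng.exponential(1.0, n) < traits.activity
            _advance(x, y, heading, active, traits.turning, 0.5, grid, rng)
            for i in range(n):
                visited[i].add((int(min(x[i], grid - 1e-9)), int(min(y[i], grid - 1e-9))))
        coverage = np.array([len(v) for v in visited])
        q = np.quantile(traits.turning, [0.25, 0.75])
        assert coverage[traits.turning <= q[0]].mean() > 2 * coverage[traits.turning >= q[1]].mean()


class TestNeighbours:
    def test_inclusive_at_exact_radius(self):
        pos = np.array([[0.0, 0.0], [0.5, 0.0]])
        assert find_neighbours(0, pos, 0.5).tolist() == [1]
        assert find_neighbours(1, pos, 0.5).tolist() == [0]

    def test_isolated_agent_has_no_neighbours(self):
        pos = np.array([[0.0, 0.0], [3.0, 0.0]])
        assert find_neighbours(0, pos, 0.5).size == 0

    def test_matches_brute_force_all_pairs_scan(self, rng):
        pos = rng.uniform(0, 10, (100, 2))
        for i in range(100):
            expected = sorted(
                j
                for j in range(100)
                if j != i and np.hypot(*(pos[i] - pos[j])) <= 0.5
            )
            assert sorted(find_neighbours(i, pos, 0.5).tolist()) == expected


class TestInteractionPhase:
    @staticmethod
    def _phase(x, y, active, activity, initiation, direction, seed=0):
        r1, r2 = (np.random.default_rng(s) for s in (seed, seed + 1))
        return interaction_phase(
            np.asarray(x, float), np.asarray(y, float),
            np.asarray(active, bool), np.asarray(activity, float),
            1, initiation, direction, r1, r2, 0.5,
        )

    def test_single_active_agent_signals_its_only_neighbour(self):
        events = self._phase(
            [0.0, 0.3], [0.0, 0.0], [True, False], [1.0, 1.0],
            InitiationRule.BY_ACTIVITY, DirectionRule.ACTIVE_OUTGOING,
        )
        assert [(e.t, e.signaller, e.receiver) for e in events] == [(1, 0, 1)]

    def test_to_active_variant_reverses_the_edge(self):
        events = self._phase(
            [0.0, 0.3], [0.0, 0.0], [True, False], [1.0, 1.0],
            InitiationRule.BY_ACTIVITY, DirectionRule.TO_ACTIVE,
        )
        assert [(e.signaller, e.receiver) for e in events] == [(1, 0)]

    def test_no_neighbours_no_events(self):
        events = self._phase(
            [0.0, 5.0], [0.0, 0.0], [True, True], [1.0, 1.0],
            InitiationRule.BY_ACTIVITY, DirectionRule.ACTIVE_OUTGOING,
        )
        assert events == []

    def test_relative_activity_direction_frequency(self):
        # P(i signals) = A_i / (A_i + A_j) = 3/4 for A = (3, 1)
        wins = 0
        trials = 20_000
        for k in range(trials):
            (ev,) = self._phase(
                [0.0, 0.3], [0.0, 0.0], [True, False], [3.0, 1.0],
                InitiationRule.BY_ACTIVITY, DirectionRule.RELATIVE_ACTIVITY,
                seed=2 * k,
            )
            wins += ev.signaller == 0
        p = wins / trials
        se = np.sqrt(0.75 * 0.25 / trials)
        assert abs(p - 0.75) < 3 * se

    def test_at_most_one_initiation_per_agent_per_step(self, small_log):
        df = small_log.to_dataframe()
        if small_log.config.direction_rule is DirectionRule.ACTIVE_OUTGOING:
            assert df.groupby(["t", "signaller"]).size().max() == 1


class TestRunSimulation:
    def test_event_invariants(self, small_log):
        assert np.all(small_log.signaller != small_log.receiver)
        assert np.all((small_log.t >= 1) & (small_log.t <= small_log.n_steps))
        assert np.all(np.diff(small_log.t) >= 0)

    def test_same_seed_byte_identical_csv(self, small_config, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        run_simulation(small_config).to_csv(a, metadata=False)
        run_simulation(small_config).to_csv(b, metadata=False)
        assert a.read_bytes() == b.read_bytes()

    def test_csv_round_trip_preserves_events(self, small_log, tmp_path):
        path = tmp_path / "log.csv"
        small_log.to_csv(path)
        back = type(small_log).from_csv(path)
        assert np.array_equal(back.t, small_log.t)
        assert np.array_equal(back.signaller, small_log.signaller)
        assert back.config == small_log.config

    def test_uniform_activity_generates_more_interactions_than_variable(self):
        """Uniform-activity colonies interact substantially more often than
        colonies whose activity levels vary across workers."""
        kw = dict(n_agents=80, n_steps=1200, grid_size=40.0)
        n_uni = len(run_simulation(SimConfig(condition=Condition.UNIFORM, seed=21, **kw)))
        n_var = len(
            run_simulation(
                SimConfig(condition=Condition.ACTIVITY_VARIABLE, seed=21, **kw)
            )
        )
        assert n_uni > 1.1 * n_var
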