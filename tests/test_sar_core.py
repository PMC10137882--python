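"""Unit and property tests for the SAR metaheuristic core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msar import (
    Bounds,
    PopulationState,
    SarConfig,
    build_clue_matrix,
    epsilon_better,
    greedy_memory_update,
    individual_phase,
    repair_bounds,
    restart_if_stuck,
    run_sar,
    social_phase,
)

from .oracles import ScriptedRng


def make_state(positions, memory, fitness, memory_fitness):
    positions = np.asarray(positions, dtype=float)
    m = positions.shape[0]
    fitness = np.asarray(fitness, dtype=float)
    best = int(np.argmax(fitness))
    return PopulationState(
        positions=positions,
        memory=np.asarray(memory, dtype=float),
        fitness=fitness,
        memory_fitness=np.asarray(memory_fitness, dtype=float),
        violations=np.zeros(m),
        memory_violations=np.zeros(m),
        usn=np.zeros(m, dtype=int),
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
        best_violation=0.0,
    )


class TestClueMatrix:
    def test_stacks_positions_then_memory(self):
        clue = build_clue_matrix([[1.0, 2.0]], [[3.0, 4.0]])
        np.testing.assert_array_equal(clue.rows, [[1.0, 2.0], [3.0, 4.0]])

    def test_duplicated_when_memory_equals_positions(self, rng):
        pos = rng.uniform(size=(4, 3))
        clue = build_clue_matrix(pos, pos)
        np.testing.assert_array_equal(clue.rows[:4], clue.rows[4:])

    def test_shape_is_2m_by_n(self, rng):
        clue = build_clue_matrix(rng.uniform(size=(3, 20)), rng.uniform(size=(3, 20)))
        assert clue.rows.shape == (6, 20)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_clue_matrix(np.zeros((2, 3)), np.zeros((3, 3)))


class TestSocialPhase:
    def setup_state(self):
        # agent 0 at [1,2,3]; clue row 1 (agent 1's position) at [4,5,6]
        state = make_state(
            positions=[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            memory=[[7.0, 8.0, 9.0], [10.0, 11.0, 12.0]],
            fitness=[0.0, 10.0],
            memory_fitness=[-5.0, -6.0],
        )
        clue = build_clue_matrix(
            state.positions, state.memory, state.fitness,
            state.memory_fitness, state.violations, state.memory_violations,
        )
        return state, clue

    def test_r1_zero_better_clue_copies_clue(self):
        state, clue = self.setup_state()
        cfg = SarConfig(pop_size=2, se=1.0, seed=0)  # SE=1: all dims update
        # draws: k raw (0 -> maps to clue 1, fitter), r1=0, r2 vector, irand
        srng = ScriptedRng(integers=[0, 0], uniforms=[0.0, [0.5, 0.5, 0.5]])
        cand = social_phase(0, state, clue, cfg, srng)
        np.testing.assert_array_equal(cand, clue.rows[1])

    def test_se_one_updates_all_dimensions(self):
        state, clue = self.setup_state()
        cfg = SarConfig(pop_size=2, se=1.0, seed=0)
        srng = ScriptedRng(integers=[0, 1], uniforms=[0.5, [0.9, 0.9, 0.9]])
        cand = social_phase(0, state, clue, cfg, srng)
        assert not np.any(cand == state.positions[0])

    def test_identical_clue_not_better_keeps_position(self):
        # clue equals X_j and is not fitter: X + r1*(X - X) = X everywhere
        state = make_state(
            positions=[[1.0, 2.0], [1.0, 2.0]],
            memory=[[1.0, 2.0], [1.0, 2.0]],
            fitness=[5.0, 5.0],
            memory_fitness=[5.0, 5.0],
        )
        clue = build_clue_matrix(
            state.positions, state.memory, state.fitness,
            state.memory_fitness, state.violations, state.memory_violations,
        )
        cfg = SarConfig(pop_size=2, se=1.0, seed=0)
        srng = ScriptedRng(integers=[0, 0], uniforms=[0.7, [0.1, 0.1]])
        cand = social_phase(0, state, clue, cfg, srng)
        np.testing.assert_array_equal(cand, state.positions[0])

    def test_at_least_one_dimension_updates(self):
        # SE=0: only the forced irand dimension may change
        state, clue = self.setup_state()
        cfg = SarConfig(pop_size=2, se=0.0, seed=0)
        srng = ScriptedRng(integers=[0, 2], uniforms=[0.5, [0.9, 0.9, 0.9]])
        cand = social_phase(0, state, clue, cfg, srng)
        changed = cand != state.positions[0]
        assert changed.sum() == 1 and changed[2]


class TestIndividualPhase:
    def test_direct_evaluation(self):
        # X_j=[0,0], Z_k=[2,4], Z_m=[1,1], r3=0.5 -> [0.5, 1.5]
        state = make_state(
            positions=[[0.0, 0.0], [2.0, 4.0]],
            memory=[[1.0, 1.0], [9.0, 9.0]],
            fitness=[0.0, 0.0],
            memory_fitness=[0.0, 0.0],
        )
        clue = build_clue_matrix(state.positions, state.memory)
        # k raw 0 -> clue 1 = [2,4]; m raw 0 -> skips {0,1} -> clue 2 = [1,1]
        srng = ScriptedRng(integers=[0, 0], uniforms=[0.5])
        cand = individual_phase(0, state, clue, srng)
        np.testing.assert_allclose(cand, [0.5, 1.5])

    def test_r3_zero_keeps_position(self):
        state = make_state(
            positions=[[3.0, 3.0], [2.0, 4.0]],
            memory=[[1.0, 1.0], [9.0, 9.0]],
            fitness=[0.0, 0.0],
            memory_fitness=[0.0, 0.0],
        )
        clue = build_clue_matrix(state.positions, state.memory)
        srng = ScriptedRng(integers=[0, 1], uniforms=[0.0])
        np.testing.assert_array_equal(
            individual_phase(0, state, clue, srng), state.positions[0]
        )

    def test_equal_clues_keep_position(self):
        state = make_state(
            positions=[[3.0, 3.0], [5.0, 5.0]],
            memory=[[5.0, 5.0], [9.0, 9.0]],
            fitness=[0.0, 0.0],
            memory_fitness=[0.0, 0.0],
        )
        clue = build_clue_matrix(state.positions, state.memory)
        # clue 1 = [5,5] and clue 2 = [5,5]: difference vanishes for any r3
        srng = ScriptedRng(integers=[0, 0], uniforms=[0.77])
        np.testing.assert_array_equal(
            individual_phase(0, state, clue, srng), state.positions[0]
        )


class TestRepairBounds:
    B = Bounds.cube(0.0, 255.0, 1)

    def test_above_upper_midpoint(self):
        out = repair_bounds(np.array([300.0]), np.array([250.0]), self.B)
        assert out[0] == 252.5

    def test_below_lower_midpoint(self):
        out = repair_bounds(np.array([-10.0]), np.array([4.0]), self.B)
        assert out[0] == 2.0

    def test_inside_unchanged(self):
        out = repair_bounds(np.array([100.0]), np.array([4.0]), self.B)
        assert out[0] == 100.0

    @given(
        cand=st.lists(st.floats(-1000, 1000), min_size=3, max_size=3),
        curr=st.lists(st.floats(0, 255), min_size=3, max_size=3),
    )
    def test_result_always_within_bounds(self, cand, curr):
        b = Bounds.cube(0.0, 255.0, 3)
        out = repair_bounds(np.array(cand), np.array(curr), b)
        assert b.contains(out)


class TestEpsilonBetter:
    def test_unconstrained_reduction_maximize(self):
        assert epsilon_better(5.0, 0.0, 3.0, 0.0)
        assert not epsilon_better(3.0, 0.0, 5.0, 0.0)

    def test_violation_dominates_outside_eps(self):
        # g1=0.5 > eps=0.2, g2 != g1 -> smaller violation wins despite fitness
        assert epsilon_better(1.0, 0.1, 5.0, 0.5, eps=0.2)

    def test_identical_pair_not_better(self):
        assert not epsilon_better(4.0, 0.3, 4.0, 0.3)

    def test_minimize_sense(self):
        assert epsilon_better(3.0, 0.0, 5.0, 0.0, sense="minimize")

    def test_negative_violation_rejected(self):
        with pytest.raises(ValueError):
            epsilon_better(1.0, -0.1, 0.0, 0.0)

    @given(
        f1=st.floats(-10, 10), f2=st.floats(-10, 10)
    )
    def test_zero_violation_is_strict_comparison(self, f1, f2):
        assert epsilon_better(f2, 0.0, f1, 0.0) == (f2 > f1)


class TestGreedyMemoryUpdate:
    def fresh(self):
        return make_state(
            positions=[[1.0, 1.0], [2.0, 2.0]],
            memory=[[3.0, 3.0], [4.0, 4.0]],
            fitness=[1.0, 2.0],
            memory_fitness=[0.0, 0.0],
        )

    def test_worse_candidate_only_increments_usn(self):
        state = self.fresh()
        cfg = SarConfig(pop_size=2)
        before_pos, before_mem = state.positions.copy(), state.memory.copy()
        greedy_memory_update(0, np.array([9.0, 9.0]), 0.5, state, ScriptedRng(), cfg)
        np.testing.assert_array_equal(state.positions, before_pos)
        np.testing.assert_array_equal(state.memory, before_mem)
        assert state.usn[0] == 1

    def test_better_candidate_accepted_and_old_position_memorized(self):
        state = self.fresh()
        cfg = SarConfig(pop_size=2)
        old = state.positions[0].copy()
        greedy_memory_update(
            0, np.array([5.0, 5.0]), 7.0, state, ScriptedRng(integers=[1]), cfg
        )
        np.testing.assert_array_equal(state.positions[0], [5.0, 5.0])
        assert state.fitness[0] == 7.0
        assert state.usn[0] == 0
        matches = [np.array_equal(state.memory[n], old) for n in range(2)]
        assert sum(matches) == 1 and matches[1]
        assert state.best_fitness == 7.0

    def test_exact_tie_rejected(self):
        state = self.fresh()
        cfg = SarConfig(pop_size=2)
        greedy_memory_update(0, np.array([5.0, 5.0]), 1.0, state, ScriptedRng(), cfg)
        np.testing.assert_array_equal(state.positions[0], [1.0, 1.0])
        assert state.usn[0] == 1


class TestRestart:
    def test_below_and_at_mu_max_unchanged(self):
        cfg = SarConfig(pop_size=2, mu_max=3)
        b = Bounds.cube(0.0, 10.0, 2)
        for usn in (0, 3):
            state = make_state(
                positions=[[1.0, 1.0], [2.0, 2.0]],
                memory=[[3.0, 3.0], [4.0, 4.0]],
                fitness=[1.0, 2.0],
                memory_fitness=[0.0, 0.0],
            )
            state.usn[0] = usn
            before = state.positions[0].copy()
            restart_if_stuck(0, state, b, cfg, np.random.default_rng(0))
            np.testing.assert_array_equal(state.positions[0], before)
            assert state.usn[0] == usn

    def test_above_mu_max_redraws_in_bounds(self):
        cfg = SarConfig(pop_size=2, mu_max=3)
        b = Bounds.cube(0.0, 10.0, 2)
        state = make_state(
            positions=[[1.0, 1.0], [2.0, 2.0]],
            memory=[[3.0, 3.0], [4.0, 4.0]],
            fitness=[1.0, 2.0],
            memory_fitness=[0.0, 0.0],
        )
        state.usn[0] = 4
        restart_if_stuck(0, state, b, cfg, np.random.default_rng(0),
                         evaluator=lambda x: (-np.sum(x**2), 0.0))
        assert b.contains(state.positions[0])
        assert state.usn[0] == 0


class TestRunSar:
    def test_constant_objective_flat_convergence(self):
        cfg = SarConfig(pop_size=5, max_iters=10, seed=0)
        res = run_sar(lambda x: 3.25, Bounds.cube(0, 1, 2), cfg)
        assert res.best_fitness == 3.25
        assert np.all(res.convergence == 3.25)

    def test_convergence_monotone_and_reaches_sphere_optimum(self):
        cfg = SarConfig(seed=1)
        res = run_sar(lambda x: -np.sum(x**2), Bounds.cube(-5, 5, 5), cfg)
        assert np.all(np.diff(res.convergence) >= 0)
        assert res.best_fitness >= -1e-2

    def test_bitwise_deterministic_across_runs(self):
        cfg = SarConfig(pop_size=10, max_iters=30, seed=7)
        f = lambda x: -np.sum((x - 1) ** 2)  # noqa: E731
        r1 = run_sar(f, Bounds.cube(-3, 3, 4), cfg)
        r2 = run_sar(f, Bounds.cube(-3, 3, 4), cfg)
        np.testing.assert_array_equal(r1.convergence, r2.convergence)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_evaluation_count_invariant(self):
        # M*(1 + 2T) + restarts; restarts are the only extra evaluations
        cfg = SarConfig(pop_size=8, max_iters=25, seed=3)
        res = run_sar(lambda x: -np.sum(x**2), Bounds.cube(-5, 5, 3), cfg)
        assert res.evaluations >= 8 * (1 + 2 * 25)

    def test_positions_stay_in_bounds_every_iteration(self):
        b = Bounds.cube(-2.0, 2.0, 3)
        seen = []

        def spy(x):
            seen.append(x.copy())
            return -np.sum(x**2)

        run_sar(spy, b, SarConfig(pop_size=6, max_iters=15, seed=5))
        # every evaluated point was already repaired into the box
        assert all(b.contains(x) for x in seen)

    def test_non_finite_objective_aborts(self):
        with pytest.raises(FloatingPointError):
            run_sar(lambda x: float("nan"), Bounds.cube(0, 1, 2),
                    SarConfig(pop_size=3, max_iters=2, seed=0))

    def test_minimize_sense_monotone_decreasing(self):
        cfg = SarConfig(pop_size=10, max_iters=50, seed=2, sense="minimize")
        res = run_sar(lambda x: np.sum(x**2), Bounds.cube(-5, 5, 3), cfg)
        assert np.all(np.diff(res.convergence) <= 0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pop_size": 1},
            {"se": 1.5},
            {"mu_max": 0},
            {"max_iters": 0},
            {"eps": -1.0},
            {"sense": "upward"},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SarConfig(**kwargs)

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            Bounds(np.array([0.0, 5.0]), np.array([1.0, 5.0]))
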