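import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from swarmsr import swarm as sw
from swarmsr.objectives import make_instance


class _FixedRng:
    """Stub generator whose uniform() always returns a constant."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        base = np.broadcast_to(self.value, size if size is not None else ())
        return low + np.asarray(base, dtype=float) * (
            np.asarray(high) - np.asarray(low)) if size is not None \
            else low + self.value * (high - low)


def sphere(x):
    return np.sum(np.atleast_2d(x) ** 2, axis=1)


class TestKinematics:
    def test_velocity_vanishes_at_consensus(self):
        x = np.ones(3)
        v = sw.update_velocity(np.ones(3), x, x, x, 0.0, 2.0, 2.0, 0.5, 0.5)
        assert np.allclose(v, 0.0)

    def test_pure_inertia_identity(self):
        v0 = np.array([1.0, -2.0])
        v = sw.update_velocity(v0, np.zeros(2), np.ones(2), np.ones(2),
                               1.0, 0.0, 0.0, 0.5, 0.5)
        assert np.array_equal(v, v0)

    def test_hand_computed_update(self):
        # w v + c1 r1 (p-x) + c2 r2 (g-x) = 0 + 1.5*.5*1 + 1.5*.5*2
        v = sw.update_velocity(0.0, 0.0, 1.0, 2.0, 0.7, 1.5, 1.5, 0.5, 0.5)
        assert v == pytest.approx(2.25)

    def test_position_advance_and_clip(self):
        x, v = sw.update_position(np.array([1.0]), np.array([2.0]),
                                  -100.0, 100.0)
        assert x[0] == 3.0 and v[0] == 2.0
        x, v = sw.update_position(np.array([99.0]), np.array([5.0]),
                                  -100.0, 100.0)
        assert x[0] == 100.0
        assert v[0] == 0.0  # clipped component loses its velocity


class TestOpposition:
    def test_centroid(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert np.allclose(sw.swarm_centroid(pts), [3.0, 4.0])
        assert np.allclose(sw.swarm_centroid(np.array([[-2.0], [2.0]])), 0.0)

    def test_opposite_is_mirror(self):
        assert np.allclose(
            sw.opposite_position(np.array([3.0, -4.0]), np.zeros(2)),
            [-3.0, 4.0])
        m = np.array([1.0, 1.0])
        assert np.allclose(sw.opposite_position(m, m), m)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, hnp.array_shapes(min_dims=2, max_dims=2,
                                                   min_side=2, max_side=12),
                      elements=st.floats(-50, 50)))
    def test_opposition_preserves_centroid(self, x):
        m = sw.swarm_centroid(x)
        ox = sw.opposite_position(x, m)
        assert np.abs(sw.swarm_centroid(ox) - m).max() < 1e-9

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(1, 10_000), st.integers(0, 10_000))
    def test_mutation_factor_stays_in_band(self, t_max, k):
        sch = sw.MutationSchedule(0.5, 0.05, t_max)
        delta = sw.mutation_factor(sch, min(k, t_max))
        assert 0.05 - 1e-12 <= delta <= 0.5 + 1e-12

    def test_dynamic_bounds(self):
        pts = np.array([[0.0, 5.0], [2.0, 1.0]])
        a, b = sw.dynamic_bounds(pts)
        assert np.array_equal(a, [0.0, 1.0]) and np.array_equal(b, [2.0, 5.0])
        m = sw.swarm_centroid(pts)
        assert np.all(a <= m) and np.all(m <= b)

    def test_repair_boundary_draws(self):
        # below the envelope with rand=0 -> the lower anchor
        out = sw.repair_opposite(np.array([-5.0]), -1.0, 1.0, 0.0,
                                 -2.0, 2.0, _FixedRng(0.0))
        assert out[0] == -2.0
        # above the envelope with rand=1 -> the upper anchor
        out = sw.repair_opposite(np.array([5.0]), -1.0, 1.0, 0.0,
                                 -2.0, 2.0, _FixedRng(1.0))
        assert out[0] == 2.0
        # in-envelope components pass through untouched
        out = sw.repair_opposite(np.array([0.5]), -1.0, 1.0, 0.0,
                                 -2.0, 2.0, _FixedRng(0.7))
        assert out[0] == 0.5


class TestSimilarity:
    def test_self_similarity_is_one(self):
        g = np.array([2.0, 1.0])
        assert sw.cosine_similarity(g, g) == pytest.approx(1.0)

    def test_orthogonal_and_oblique(self):
        assert sw.cosine_similarity([1.0, 0.0], [0.0, 3.0]) == \
            pytest.approx(0.0)
        assert sw.cosine_similarity([1.0, 0.0], [1.0, 1.0]) == \
            pytest.approx(1 / np.sqrt(2), abs=1e-5)

    def test_zero_norm_defined_as_zero(self):
        assert sw.cosine_similarity(np.zeros(3), np.ones(3)) == 0.0

    def test_mean_similarity(self):
        g = np.array([1.0, 0.0])
        pos = np.array([[2.0, 0.0], [0.0, 1.0]])  # sims 1 and 0
        assert sw.mean_similarity(g, pos) == pytest.approx(0.5)
        assert -1.0 <= sw.mean_similarity(g, pos) <= 1.0


class TestMutation:
    def test_schedule_endpoints_and_midpoint(self):
        sch = sw.MutationSchedule(0.5, 0.05, 100)
        assert sw.mutation_factor(sch, 0) == pytest.approx(0.50)
        assert sw.mutation_factor(sch, 100) == pytest.approx(0.05)
        assert sw.mutation_factor(sch, 50) == pytest.approx(0.275)

    def test_out_of_range_clamped(self):
        sch = sw.MutationSchedule(0.5, 0.05, 10)
        assert sw.mutation_factor(sch, 99) == pytest.approx(0.05)
        assert sw.mutation_factor(sch, -1) == pytest.approx(0.5)

    def _state(self, positions):
        vals = sphere(positions)
        i = int(np.argmin(vals))
        return sw.SwarmState(
            positions=positions.copy(),
            velocities=np.zeros_like(positions), values=vals,
            pbest_positions=positions.copy(), pbest_values=vals.copy(),
            gbest_position=positions[i].copy(), gbest_value=float(vals[i]),
            gbest_index=i)

    def test_zero_probability_mutates_nothing(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-1, 1, (20, 3))
        state = self._state(pos)
        sch = sw.MutationSchedule(0.0, 0.0, 10)
        state, n = sw.mutation_sweep(state, sch, -1.0, 1.0, sphere, rng)
        assert n == 0
        assert np.array_equal(state.positions, pos)

    def test_mutated_count_is_binomial(self):
        # half the swarm aggregated near gbest, half anti-aligned: the
        # aggregated half is the mutation region; delta = 0.5
        rng = np.random.default_rng(7)
        n_half = 500
        near = np.tile([10.0, 0.0], (n_half, 1)) + rng.normal(0, .01,
                                                              (n_half, 2))
        far = np.tile([-10.0, 0.0], (n_half, 1)) + rng.normal(0, .01,
                                                              (n_half, 2))
        state = self._state(np.vstack([near, far]))
        sch = sw.MutationSchedule(0.5, 0.5, 10)
        before = state.gbest_value
        state, n_mut = sw.mutation_sweep(state, sch, -100.0, 100.0, sphere,
                                         rng)
        p, n_region = 0.5, n_half - 1  # gbest holder exempt
        sigma = np.sqrt(n_region * p * (1 - p))
        assert abs(n_mut - n_region * p) < 3 * sigma
        assert state.gbest_value <= before  # incumbent survives


class TestCoblStep:
    def test_mirror_adopted_when_better(self):
        # f(x) = (x-1)^2; particle at -1 mirrors across M=0.5 to 2 (better)
        f = lambda x: (np.atleast_2d(x)[:, 0] - 1.0) ** 2
        pos = np.array([[-1.0], [2.0]])
        vals = f(pos)
        state = sw.SwarmState(
            positions=pos.copy(), velocities=np.ones((2, 1)), values=vals,
            pbest_positions=pos.copy(), pbest_values=vals.copy(),
            gbest_position=pos[1].copy(), gbest_value=float(vals[1]),
            gbest_index=1)
        before = state.gbest_value
        state = sw.cobl_step(state, f, np.random.default_rng(0))
        assert state.positions[0, 0] == pytest.approx(2.0)
        assert state.velocities[0, 0] == 0.0  # motion restarts on adoption
        assert state.positions[1, 0] == pytest.approx(2.0)  # not replaced
        assert state.gbest_value <= before


class TestMinimize:
    def test_sphere_converges(self):
        cfg = sw.SwarmConfig(n_particles=20, eval_budget=4000,
                             algorithm="smcpso", seed=1)
        res = sw.minimize(sphere, -5.0, 5.0, 2, cfg)
        assert res.best_value <= 1e-4

    @pytest.mark.parametrize("alg", ["pso", "cobl", "smcpso"])
    def test_gbest_monotone_and_consistent(self, alg):
        inst = make_instance("F11", 5, 0)
        cfg = sw.SwarmConfig(n_particles=10, eval_budget=2000,
                             algorithm=alg, seed=2)
        res = sw.minimize(inst, inst.lower, inst.upper, 5, cfg)
        g = [h["gbest_value"] for h in res.history]
        assert all(b <= a + 1e-12 for a, b in zip(g, g[1:]))
        # the reported optimum re-evaluates to the reported value
        assert abs(float(inst(res.best_position[None])[0])
                   - res.best_value) < 1e-9
        assert res.evals_used <= cfg.eval_budget

    def test_bit_reproducible(self):
        cfg = sw.SwarmConfig(n_particles=12, eval_budget=1500,
                             algorithm="smcpso", seed=9)
        a = sw.minimize(sphere, -3.0, 3.0, 4, cfg)
        b = sw.minimize(sphere, -3.0, 3.0, 4, cfg)
        assert np.array_equal(a.best_position, b.best_position)
        assert a.best_value == b.best_value
        assert a.history == b.history

    def test_budget_too_small_rejected(self):
        cfg = sw.SwarmConfig(n_particles=40, eval_budget=10)
        with pytest.raises(ValueError, match="budget"):
            sw.minimize(sphere, -1.0, 1.0, 2, cfg)

    def test_iteration_mode_runs_exact_count(self):
        cfg = sw.SwarmConfig(n_particles=5, eval_budget=None,
                             max_iterations=37, algorithm="pso", seed=0)
        res = sw.minimize(sphere, -1.0, 1.0, 3, cfg)
        assert len(res.history) == 37

    def test_init_positions_respected(self):
        init = np.full((5, 2), 0.25)
        cfg = sw.SwarmConfig(n_particles=5, eval_budget=None,
                             max_iterations=1, algorithm="pso", seed=0)
        res = sw.minimize(sphere, -1.0, 1.0, 2, cfg, init_positions=init)
        assert res.best_value <= sphere(init)[0] + 1e-12
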