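"""Leech optimizer: chaotic map, OBL, strategy iteration, full runs."""

import numpy as np
import pytest

from ppcml import benchmarks
from ppcml import optimizer as opt


def sphere(X):
    return (np.atleast_2d(X) ** 2).sum(axis=1)


def config(**kw):
    base = dict(dim=5, bounds=(-100.0, 100.0), population_size=20,
                max_iterations=50, seed=0, variant="ibslo")
    base.update(kw)
    return opt.OptimizerConfig(**base)


class TestCubicMap:
    def test_hand_computed_recursion(self):
        # z1 = 2.595 * 0.3 * (1 - 0.09) = 0.708435, then iterate by hand
        seq = opt.cubic_map_sequence(0.3, 3, rho=2.595)
        z1 = 2.595 * 0.3 * (1 - 0.3 ** 2)
        z2 = 2.595 * z1 * (1 - z1 ** 2)
        z3 = 2.595 * z2 * (1 - z2 ** 2)
        assert seq == pytest.approx([z1, z2, z3], abs=1e-15)
        assert seq[0] == pytest.approx(0.708435)

    @pytest.mark.parametrize("z0", [0.05, 0.3, 0.62, 0.9])
    def test_orbit_stays_in_open_unit_interval(self, z0):
        seq = opt.cubic_map_sequence(z0, 10_000)
        assert (seq > 0).all() and (seq < 1).all()

    def test_sensitive_dependence_on_initial_condition(self):
        a = opt.cubic_map_sequence(0.3, 200)
        b = opt.cubic_map_sequence(0.3 + 1e-6, 200)
        tail_corr = np.corrcoef(a[100:], b[100:])[0, 1]
        assert abs(tail_corr) < 0.5

    def test_invalid_start_rejected(self):
        with pytest.raises(ValueError):
            opt.cubic_map_sequence(0.0, 5)
        with pytest.raises(ValueError):
            opt.cubic_map_sequence(1.2, 5)


class TestOppositePoint:
    def test_midpoint_is_fixed_point(self):
        a, b = np.zeros(3), np.ones(3)
        x = np.full(3, 0.5)
        assert np.allclose(opt.opposite_point(x, a, b), x)

    def test_involution(self, rng):
        a = rng.uniform(-5, 0, size=8)
        b = rng.uniform(1, 5, size=8)
        x = rng.uniform(a, b)
        assert np.allclose(opt.opposite_point(opt.opposite_point(x, a, b), a, b), x)

    def test_boundary_maps_to_boundary(self):
        a, b = np.array([-2.0]), np.array([3.0])
        assert opt.opposite_point(a, a, b) == pytest.approx(b)

    def test_outside_point_clamped_first(self):
        a, b = np.array([0.0]), np.array([1.0])
        assert opt.opposite_point(np.array([2.0]), a, b) == pytest.approx(0.0)


class TestChaoticInit:
    def test_positions_within_bounds(self):
        pop = opt.initialize_population_chaotic(config(), sphere)
        assert (pop.positions >= -100).all() and (pop.positions <= 100).all()

    def test_unit_bounds_reproduce_raw_chaotic_values(self):
        cfg = config(bounds=(0.0, 1.0))
        pop = opt.initialize_population_chaotic(cfg, sphere)
        rng = np.random.default_rng(cfg.seed)
        z0 = rng.uniform(0.05, 0.95)
        z = opt.cubic_map_sequence(z0, cfg.population_size * cfg.dim,
                                   cfg.chaotic_rho)
        assert np.allclose(pop.positions.ravel(), z)

    def test_deterministic(self):
        p1 = opt.initialize_population_chaotic(config(), sphere)
        p2 = opt.initialize_population_chaotic(config(), sphere)
        assert np.array_equal(p1.positions, p2.positions)

    def test_diversity_comparable_to_uniform(self):
        # chaotic init must not collapse the population's spread
        from scipy.spatial.distance import pdist

        cfg = config(dim=10, population_size=30)
        chaotic = opt.initialize_population_chaotic(cfg, sphere).positions
        uniform = np.random.default_rng(123).uniform(-100, 100, size=(30, 10))
        assert pdist(chaotic).mean() >= 0.8 * pdist(uniform).mean()


class TestDynamicObl:
    def test_zero_probability_is_identity(self):
        pop = opt.initialize_population_chaotic(config(), sphere)
        rng = np.random.default_rng(1)
        out = opt.dynamic_obl_step(pop, sphere, rng, obl_probability=0.0)
        assert out is pop

    def test_elitist_union_selection_matches_sort_oracle(self):
        cfg = config(seed=4)
        pop = opt.initialize_population_chaotic(cfg, sphere)
        rng = np.random.default_rng(9)
        lo, hi = pop.positions.min(axis=0), pop.positions.max(axis=0)
        union_fitness = np.concatenate(
            [pop.fitness, sphere(opt.opposite_point(pop.positions, lo, hi))]
        )
        expected = np.sort(union_fitness)[: len(pop.fitness)]
        out = opt.dynamic_obl_step(pop, sphere, rng, obl_probability=1.0)
        assert np.allclose(np.sort(out.fitness), expected)

    def test_never_degrades_best(self):
        for seed in range(5):
            pop = opt.initialize_population_chaotic(config(seed=seed), sphere)
            rng = np.random.default_rng(seed)
            out = opt.dynamic_obl_step(pop, sphere, rng, obl_probability=1.0)
            assert out.best_fitness <= pop.best_fitness


class TestBsloIteration:
    def test_population_at_optimum_stays(self):
        cfg = config(dim=3)
        positions = np.zeros((cfg.population_size, 3))
        pop = opt.Population(
            positions=positions, fitness=sphere(positions),
            best_position=np.zeros(3), best_fitness=0.0,
        )
        rng = np.random.default_rng(0)
        out = opt.bslo_iteration(pop, cfg, sphere, rng)
        assert out.best_fitness == 0.0

    def test_best_never_worsens_across_iterations(self):
        cfg = config(max_iterations=30)
        pop = opt.initialize_population_chaotic(cfg, sphere)
        rng = np.random.default_rng(2)
        best = pop.best_fitness
        for _ in range(30):
            pop = opt.bslo_iteration(pop, cfg, sphere, rng)
            assert pop.best_fitness <= best
            best = pop.best_fitness

    def test_positions_respect_bounds(self):
        cfg = config(bounds=(-1.0, 2.0))
        pop = opt.initialize_population_chaotic(cfg, sphere)
        rng = np.random.default_rng(5)
        for _ in range(20):
            pop = opt.bslo_iteration(pop, cfg, sphere, rng)
            assert (pop.positions >= -1.0).all() and (pop.positions <= 2.0).all()


class TestOptimize:
    @pytest.mark.parametrize("variant", ["bslo", "ibslo"])
    def test_history_monotone_nonincreasing(self, variant):
        res = opt.optimize(sphere, config(variant=variant, max_iterations=80))
        assert (np.diff(res.history) <= 1e-300).all() or (
            np.diff(res.history) <= 0
        ).all()

    @pytest.mark.parametrize("variant", ["bslo", "ibslo"])
    def test_deterministic_under_seed(self, variant):
        r1 = opt.optimize(sphere, config(variant=variant, seed=7))
        r2 = opt.optimize(sphere, config(variant=variant, seed=7))
        assert r1.best_fitness == r2.best_fitness
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.history, r2.history)

    def test_single_iteration_history_length(self):
        res = opt.optimize(sphere, config(max_iterations=1))
        assert len(res.history) == 1

    def test_sphere_convergence_both_variants(self):
        # 2-D sphere, 30 leeches, 200 iterations: median over 10 seeds well
        # below 1e-2 (known optimum 0)
        for variant in ("bslo", "ibslo"):
            finals = [
                opt.optimize(
                    sphere,
                    config(dim=2, population_size=30, max_iterations=200,
                           seed=s, variant=variant),
                ).best_fitness
                for s in range(10)
            ]
            assert np.median(finals) < 1e-2

    def test_warm_start_candidates_enter_population(self):
        cfg = config(dim=3, bounds=(0.0, 1.0), max_iterations=1)
        seeds = np.array([[0.5, 0.5, 0.5]])
        res = opt.optimize(sphere, cfg, initial_candidates=seeds)
        assert res.best_fitness <= sphere(seeds)[0]

    def test_benchmark_function_objective(self):
        f = benchmarks.make_suite(5, seed=8)[0]
        res = opt.optimize(
            lambda X: benchmarks.evaluate_batch(f, X),
            config(dim=5, max_iterations=100, seed=3),
        )
        assert res.best_fitness >= f.f_opt
        assert res.evaluations > 0


class TestConfigValidation:
    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            config(population_size=3)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            config(bounds=(5.0, -5.0))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            config(variant="pso")
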