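"""Evolutionary wrapper feature selection: fitness, operators, search."""

import itertools

import numpy as np
import pytest

from docndf import (FeatureTable, FitnessEvaluator, Individual, MFFSConfig,
                    environmental_selection, explicit_transfer, fitness,
                    generate_offspring, pareto_front, run_mffs, scalarize)


def make_table(seed, n=40, p=8, k_inf=3, shift=1.2):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.standard_normal((n, p))
    X[:, :k_inf] += shift * y[:, None]
    return FeatureTable(X=X, y=y, feature_names=[f"f{i}" for i in range(p)])


def separable_table():
    y = np.array([0] * 10 + [1] * 10)
    X = np.column_stack([y * 10.0, np.zeros(20)])
    X[:, 1] = np.arange(20) % 3  # irrelevant
    return FeatureTable(X=X, y=y, feature_names=["good", "junk"])


class TestFitness:
    def test_separable_feature_gives_zero_error(self):
        table = separable_table()
        cfg = MFFSConfig(subpop_size=4, iterations=1, cv_folds=5, seed=0)
        err, frac = fitness(np.array([1, 0], dtype=np.uint8), table, cfg)
        assert err == 0.0 and frac == 0.5

    def test_empty_subset_convention(self):
        table = separable_table()
        cfg = MFFSConfig(subpop_size=4, iterations=1, seed=0)
        err, frac = fitness(np.zeros(2, dtype=np.uint8), table, cfg)
        assert err == 1.0 and frac == 0.0

    def test_pure_noise_is_chance_level(self):
        errs = []
        for seed in range(20):
            table = make_table(seed, n=40, p=4, k_inf=0)
            cfg = MFFSConfig(subpop_size=4, iterations=1, seed=seed)
            errs.append(fitness(np.ones(4, dtype=np.uint8), table, cfg)[0])
        assert 0.35 <= np.mean(errs) <= 0.65

    def test_cache_returns_identical_values(self):
        table = make_table(0)
        cfg = MFFSConfig(subpop_size=4, iterations=1, seed=0)
        ev = FitnessEvaluator(table, cfg)
        bits = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=np.uint8)
        assert ev(bits) == ev(bits.copy())


class TestGenerateOffspring:
    def _pop(self, rng, size=6, L=8):
        return [Individual((rng.uniform(size=L) < 0.5).astype(np.uint8),
                           (rng.uniform(), rng.uniform()))
                for _ in range(size)]

    def test_noop_genetics_copies_parents(self, rng):
        pop = self._pop(rng)
        cfg = MFFSConfig(subpop_size=6, iterations=1, crossover_prob=0.0,
                         mutation_prob=0.0, implicit_transfer_prob=0.0)
        kids = generate_offspring(pop, pop, cfg, np.random.default_rng(0))
        parent_bits = {ind.bits.tobytes() for ind in pop}
        assert all(k.tobytes() in parent_bits for k in kids)

    def test_full_mutation_flips_every_bit(self):
        pop = [Individual(np.zeros(4, dtype=np.uint8), (0.5, 0.0))]
        cfg = MFFSConfig(subpop_size=2, iterations=1, crossover_prob=0.0,
                         mutation_prob=1.0, implicit_transfer_prob=0.0)
        kids = generate_offspring(pop, pop, cfg, np.random.default_rng(0))
        for k in kids:
            assert np.array_equal(k, np.ones(4, dtype=np.uint8))

    def test_seeded_determinism(self, rng):
        pop = self._pop(rng)
        cfg = MFFSConfig(subpop_size=6, iterations=1)
        a = generate_offspring(pop, pop, cfg, np.random.default_rng(3))
        b = generate_offspring(pop, pop, cfg, np.random.default_rng(3))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestExplicitTransfer:
    def _pop(self, rng, size=8):
        return [Individual((rng.uniform(size=6) < 0.5).astype(np.uint8),
                           (rng.uniform(), rng.uniform()))
                for _ in range(size)]

    def test_zero_elites_unchanged(self, rng):
        a, b = self._pop(rng), self._pop(rng)
        na, nb = explicit_transfer(a, b, 0)
        assert [i.objectives for i in na] == [i.objectives for i in a]

    def test_full_transfer_swaps_populations(self, rng):
        a, b = self._pop(rng), self._pop(rng)
        na, nb = explicit_transfer(a, b, 8)
        assert sorted(i.objectives for i in na) == sorted(
            i.objectives for i in b)
        assert sorted(i.objectives for i in nb) == sorted(
            i.objectives for i in a)

    def test_best_scalarized_fitness_never_worsens(self, rng):
        for _ in range(10):
            a, b = self._pop(rng), self._pop(rng)
            best_a = min(scalarize(i.objectives) for i in a)
            best_b = min(scalarize(i.objectives) for i in b)
            na, nb = explicit_transfer(a, b, 3)
            assert min(scalarize(i.objectives) for i in na) <= best_a
            assert min(scalarize(i.objectives) for i in nb) <= best_b
            assert len(na) == len(a) and len(nb) == len(b)


class TestEnvironmentalSelection:
    def test_chebyshev_hand_value(self):
        assert scalarize((0.2, 0.5), weights=(0.5, 0.5)) == pytest.approx(0.25)

    def test_dominating_member_retained(self, rng):
        union = [Individual((rng.uniform(size=4) < 0.5).astype(np.uint8),
                            (rng.uniform(0.3, 1.0), rng.uniform(0.3, 1.0)))
                 for _ in range(12)]
        star = Individual(np.ones(4, dtype=np.uint8), (0.1, 0.1))
        union.append(star)
        cfg = MFFSConfig(subpop_size=6, iterations=1)
        kept = environmental_selection(union, cfg)
        assert any(ind.objectives == (0.1, 0.1) for ind in kept)

    def test_output_size_exact(self, rng):
        union = [Individual((rng.uniform(size=4) < 0.5).astype(np.uint8),
                            (rng.uniform(), rng.uniform()))
                 for _ in range(20)]
        cfg = MFFSConfig(subpop_size=8, iterations=1)
        assert len(environmental_selection(union, cfg)) == 8


class TestRunMffs:
    def test_more_iterations_never_worse(self):
        table = make_table(2)
        short = run_mffs(table, MFFSConfig(subpop_size=10, iterations=1,
                                           elite_count=2, seed=5))
        long = run_mffs(table, MFFSConfig(subpop_size=10, iterations=10,
                                          elite_count=2, seed=5))
        assert long.cv_error <= short.cv_error

    def test_seeded_determinism(self):
        table = make_table(3)
        cfg = MFFSConfig(subpop_size=10, iterations=5, elite_count=2, seed=11)
        a, b = run_mffs(table, cfg), run_mffs(table, cfg)
        assert np.array_equal(a.bits, b.bits)
        assert a.cv_error == b.cv_error

    def test_front_is_mutually_non_dominated(self):
        table = make_table(4)
        sol = run_mffs(table, MFFSConfig(subpop_size=10, iterations=5,
                                         elite_count=2, seed=0))
        objs = [o for _, o in sol.front]
        for f in objs:
            for g in objs:
                if f != g:
                    assert not (g[0] <= f[0] and g[1] <= f[1]
                                and (g[0] < f[0] or g[1] < f[1]))

    def test_best_so_far_monotone_over_generations(self):
        table = make_table(5)
        sol = run_mffs(table, MFFSConfig(subpop_size=10, iterations=8,
                                         elite_count=2, seed=1))
        assert all(b <= a + 1e-12 for a, b in zip(sol.history,
                                                  sol.history[1:]))

    def test_matches_exhaustive_search_on_small_problems(self):
        """Search returns the exhaustive-search optimum CV error under
        shared folds on a few small tables (full sweep in acceptance)."""
        hits = 0
        for seed in range(5):
            table = make_table(seed)
            cfg = MFFSConfig(subpop_size=20, iterations=30, elite_count=2,
                             seed=seed)
            ev = FitnessEvaluator(table, cfg)
            best = min(ev(np.array(b, dtype=np.uint8))[0]
                       for b in itertools.product([0, 1], repeat=8)
                       if any(b))
            sol = run_mffs(table, cfg)
            hits += abs(sol.cv_error - best) < 1e-12
        assert hits >= 4

    def test_pareto_front_helper(self):
        pop = [Individual(np.array([1], dtype=np.uint8), o)
               for o in [(0.1, 0.5), (0.2, 0.2), (0.3, 0.1), (0.3, 0.3),
                         (0.4, 0.4)]]
        front = {i.objectives for i in pareto_front(pop)}
        assert front == {(0.1, 0.5), (0.2, 0.2), (0.3, 0.1)}
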