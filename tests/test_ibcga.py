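from itertools import product

import numpy as np
import pytest

from pcpselect.ibcga import (
    Chromosome,
    GAConfig,
    build_oa,
    evolve_r,
    inherit,
    init_population,
    med_ranking,
    oa_crossover,
    run_ibcga,
)


def small_cfg(**kw):
    base = dict(r_start=3, r_end=3, pop_size=12, stop_idle=5, max_gen=25, seed=0)
    base.update(kw)
    return GAConfig(**base)


class TestInitPopulation:
    def test_exact_r_everywhere(self):
        rng = np.random.default_rng(0)
        pop = init_population(10, 3, small_cfg(pop_size=5), rng)
        assert all(c.r == 3 for c in pop)
        assert all(0 <= c.gamma_code <= 15 and 0 <= c.cost_code <= 15 for c in pop)

    def test_r_equals_n_all_ones(self):
        rng = np.random.default_rng(1)
        pop = init_population(6, 6, small_cfg(pop_size=3), rng)
        assert all(c.genes.all() for c in pop)

    def test_r_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            init_population(5, 6, small_cfg(), np.random.default_rng(0))

    def test_uniform_placement_binomial(self):
        # each position selected with probability r/n = 0.3 over many draws
        rng = np.random.default_rng(2)
        cfg = small_cfg(pop_size=10_000)
        pop = init_population(10, 3, cfg, rng)
        freq = np.mean([c.genes for c in pop], axis=0)
        sigma = np.sqrt(0.3 * 0.7 / 10_000)
        assert np.all(np.abs(freq - 0.3) < 3 * sigma + 1e-12)


class TestOrthogonalArray:
    def test_l4_rows(self):
        oa = build_oa(3)
        assert oa.shape == (4, 3)
        assert {tuple(r) for r in oa} == {(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)}

    def test_l8_column_balance(self):
        oa = build_oa(7)
        assert oa.shape == (8, 7)
        assert np.all(oa.sum(axis=0) == 4)

    @pytest.mark.parametrize("k", range(2, 16))
    def test_strength_two_exhaustive(self, k):
        oa = build_oa(k)
        M = oa.shape[0]
        for a in range(k):
            for b in range(a + 1, k):
                pairs = [tuple(p) for p in oa[:, [a, b]]]
                for combo in product((0, 1), repeat=2):
                    assert pairs.count(combo) == M // 4


def flat_fitness(genes, g, c):
    return 0.0


class TestOaCrossover:
    def test_identical_parents_fixed_point(self):
        rng = np.random.default_rng(3)
        genes = np.zeros(12, bool)
        genes[[1, 5, 9]] = True
        p = Chromosome(genes, 4, 11)
        c1, c2 = oa_crossover(p, p.copy(), 4, flat_fitness, rng)
        for c in (c1, c2):
            np.testing.assert_array_equal(c.genes, p.genes)
            assert (c.gamma_code, c.cost_code) == (4, 11)

    def test_popcount_preserved_with_repair(self):
        rng = np.random.default_rng(4)
        rnd = np.random.default_rng(5)

        def noisy(genes, g, c):
            return float(rnd.random())

        for _ in range(10):
            g1 = np.zeros(20, bool)
            g1[rng.choice(20, 6, replace=False)] = True
            g2 = np.zeros(20, bool)
            g2[rng.choice(20, 6, replace=False)] = True
            c1, c2 = oa_crossover(
                Chromosome(g1, 0, 0), Chromosome(g2, 15, 15), 5, noisy, rng
            )
            assert c1.r == 6 and c2.r == 6

    def test_unequal_parent_sizes_rejected(self):
        g1 = np.zeros(8, bool)
        g1[:3] = True
        g2 = np.zeros(8, bool)
        g2[:4] = True
        with pytest.raises(ValueError):
            oa_crossover(
                Chromosome(g1, 0, 0), Chromosome(g2, 0, 0), 3, flat_fitness,
                np.random.default_rng(0),
            )

    def test_reasoned_child_equals_blockwise_argmax_on_additive_fitness(self):
        # 4 blocks of 2 positions; both parents have one 1 per block, so any
        # block mix keeps popcount 4 and no repair can interfere
        rng = np.random.default_rng(6)
        k = 4
        w = np.random.default_rng(7).random((k, 2))  # w[block, parent]

        p1 = Chromosome(np.array([1, 0] * k, bool), 0, 0)
        p2 = Chromosome(np.array([0, 1] * k, bool), 0, 0)

        def block_levels(genes):
            # level 0 = pattern of p1 ([1,0]), level 1 = p2 ([0,1])
            return [int(genes[2 * b + 1]) for b in range(k)]

        def fitness(genes, g, c):
            return float(sum(w[b, lv] for b, lv in enumerate(block_levels(genes))))

        _, reasoned = oa_crossover(p1, p2, k, fitness, rng)
        # brute force over all 2^k block combinations
        best = max(product((0, 1), repeat=k), key=lambda lv: sum(w[b, l] for b, l in enumerate(lv)))
        assert tuple(block_levels(reasoned.genes)) == best
        assert reasoned.fitness == pytest.approx(sum(w[b, l] for b, l in enumerate(best)))


class TestEvolve:
    def test_recovers_planted_triplet(self):
        planted = {2, 9, 17}

        def fitness(genes, g, c):
            return len(planted & set(np.nonzero(genes)[0])) / 3

        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cfg = small_cfg(seed=seed)
            pop = init_population(20, 3, cfg, rng)
            best, _ = evolve_r(pop, cfg, fitness, rng)
            hits += best.fitness == 1.0 and set(np.nonzero(best.genes)[0]) == planted
        assert hits >= 9

    def test_identical_population_no_mutation_fixed_point(self):
        genes = np.zeros(10, bool)
        genes[:3] = True
        pop = [Chromosome(genes.copy(), 5, 5) for _ in range(8)]

        def fitness(genes, g, c):
            return float(genes[:3].sum())

        cfg = small_cfg(pop_size=8, p_m=0.0, max_gen=5)
        best, final = evolve_r(pop, cfg, fitness, np.random.default_rng(0))
        np.testing.assert_array_equal(best.genes, genes)
        for c in final:
            np.testing.assert_array_equal(c.genes, genes)

    def test_best_fitness_monotone_nondecreasing(self):
        rnd = np.random.default_rng(8)
        table = {}

        def fitness(genes, g, c):
            key = genes.tobytes()
            if key not in table:
                table[key] = float(rnd.random())
            return table[key]

        rng = np.random.default_rng(9)
        cfg = small_cfg(pop_size=10, max_gen=15, stop_idle=20)
        pop = init_population(15, 4, cfg, rng)
        trace = []
        evolve_r(pop, cfg, fitness, rng, trace=trace)
        assert all(b <= a + 1e-12 for b, a in zip(trace, trace[1:]))


class TestInheritance:
    def test_popcount_increments_by_one(self):
        rng = np.random.default_rng(10)
        cfg = small_cfg(pop_size=6)
        pop = init_population(12, 4, cfg, rng)
        new = inherit(pop, rng)
        assert all(c.r == 5 for c in new)
        # inherited genes are a superset of the parent's
        for old, nw in zip(pop, new):
            assert np.all(nw.genes[old.genes])

    def test_single_r_solution_set(self):
        def fitness(genes, g, c):
            return float(genes[:2].sum())

        cfg = small_cfg(r_start=5, r_end=5, pop_size=8, max_gen=5)
        sol = run_ibcga(12, cfg, fitness)
        assert sol.sizes() == [5]
        assert sol.best[5].r == 5

    def test_fitness_plateau_after_planted_size(self):
        planted = {0, 1, 2, 3, 4}

        def fitness(genes, g, c):
            return len(planted & set(np.nonzero(genes)[0])) / 5

        cfg = GAConfig(r_start=3, r_end=8, pop_size=16, stop_idle=4, max_gen=20, seed=11)
        sol = run_ibcga(60, cfg, fitness, seed=11)
        fits = [sol.best[r].fitness for r in sol.sizes()]
        assert fits[-1] == 1.0  # r=8 can cover all 5 planted
        assert all(b >= a - 1e-12 for a, b in zip(fits, fits[1:]))

    def test_run_deterministic_under_seed(self):
        def fitness(genes, g, c):
            return float(genes[::2].sum()) + 0.01 * g

        cfg = small_cfg(r_start=2, r_end=4, pop_size=8, max_gen=6)
        a = run_ibcga(10, cfg, fitness, seed=21)
        b = run_ibcga(10, cfg, fitness, seed=21)
        for r in a.sizes():
            np.testing.assert_array_equal(a.best[r].genes, b.best[r].genes)
            assert a.best[r].fitness == b.best[r].fitness


class TestSubsetFitness:
    def test_matches_cv_fitness_on_random_subsets(self):
        """The kernel-caching fitness oracle must agree exactly with the
        reference cross-validation evaluator on the same folds."""
        from pcpselect.ibcga import feature_subset_fitness
        from pcpselect.svm_eval import SvmParams, cv_fitness, make_folds

        rng = np.random.default_rng(30)
        X = rng.uniform(-1, 1, size=(60, 12))
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        X[y == 1, :3] += 0.4
        fit = feature_subset_fitness(X, y, seed=31)
        splits = make_folds(y, 5, 31)
        for _ in range(15):
            genes = np.zeros(12, bool)
            genes[rng.choice(12, 4, replace=False)] = True
            g, c = int(rng.integers(16)), int(rng.integers(16))
            expect = cv_fitness(
                X[:, genes], y, SvmParams.from_codes(g, c), fold_splits=splits
            ).accuracy
            assert fit(genes, g, c) == expect

    def test_reseed_changes_folds_deterministically(self):
        from pcpselect.ibcga import feature_subset_fitness

        rng = np.random.default_rng(32)
        X = rng.uniform(-1, 1, size=(40, 6))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        X[y == 1, 0] += 0.3
        genes = np.ones(6, bool)
        a = feature_subset_fitness(X, y, seed=1)
        b = feature_subset_fitness(X, y, seed=1)
        assert a(genes, 7, 7) == b(genes, 7, 7)
        a.reseed(99)
        b.reseed(99)
        assert a(genes, 7, 7) == b(genes, 7, 7)


class TestMedRanking:
    def test_indicator_fitness(self):
        ids = ["f0", "f1", "f2", "f3"]

        def eval_subset(keep):
            return 1.0 if 0 in keep else 0.0

        rep = med_ranking(ids, eval_subset)
        assert rep.med[0] == pytest.approx(1.0)
        np.testing.assert_allclose(rep.med[1:], 0.0, atol=1e-12)
        assert rep.ranks[0] == 1

    def test_additive_weights_match_full_factorial_oracle(self):
        w = [0.5, 0.3, 0.2]

        def eval_subset(keep):
            return sum(w[i] for i in keep)

        rep = med_ranking(["a", "b", "c"], eval_subset)
        # oracle: full 2^3 factorial main effects
        oracle = []
        for j in range(3):
            kept, removed = [], []
            for mask in product((0, 1), repeat=3):
                v = sum(w[i] for i in range(3) if mask[i] == 0)
                (kept if mask[j] == 0 else removed).append(v)
            oracle.append(abs(np.mean(kept) - np.mean(removed)))
        np.testing.assert_allclose(rep.med, w, atol=1e-12)
        np.testing.assert_allclose(rep.med, oracle, atol=1e-12)
        assert list(rep.ranks) == [1, 2, 3]

    def test_permutation_consistency(self):
        w = {"a": 0.1, "b": 0.7, "c": 0.4}

        def make_eval(ids):
            return lambda keep: sum(w[ids[i]] for i in keep)

        ids1 = ["a", "b", "c"]
        ids2 = ["c", "a", "b"]
        r1 = med_ranking(ids1, make_eval(ids1))
        r2 = med_ranking(ids2, make_eval(ids2))
        assert dict(zip(ids1, r1.ranks))["b"] == 1
        m1 = dict(zip(ids1, r1.med))
        m2 = dict(zip(ids2, r2.med))
        for key in w:
            assert m1[key] == pytest.approx(m2[key], abs=1e-12)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            med_ranking(["only"], lambda keep: 0.0)
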