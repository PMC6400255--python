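import numpy as np
import pytest

import gamerge as gm
from gamerge import (
    Chromosome,
    FitnessWeights,
    GAConfig,
    balance_weights,
    chromosome_fitness,
    crossover,
    evolve,
    exhaustive_oracle,
    group_score,
    initialize_population,
    mutate,
    random_control,
)
from gamerge.ga import _restricted_growth_strings
from gamerge.merging import MergingStats, ShellTriple

from conftest import small_synthetic_config


def make_stats(r_meas_inner=0.1, r_meas_overall=0.2, i_sig=20.0, cc_anom=0.1,
               cc_half=0.99, compl=0.9, mult=10.0):
    def t(v):
        return ShellTriple(v, v, v)

    return MergingStats(
        r_merge=t(0.1),
        r_meas=ShellTriple(r_meas_inner, r_meas_overall, r_meas_overall),
        i_over_sigma=t(i_sig), cc_half=t(cc_half), cc_anom=t(cc_anom),
        sig_ano=t(1.0), completeness=t(compl), multiplicity=t(mult),
    )


class FakeRNG:
    """Deterministic stand-in for a Generator in operator unit tests."""

    def __init__(self, integers=(), randoms=()):
        self._ints = list(integers)
        self._rands = list(randoms)

    def integers(self, low, high=None, size=None):
        v = self._ints.pop(0)
        return np.asarray(v) if size is not None else v

    def random(self, size=None):
        v = self._rands.pop(0)
        return np.asarray(v) if size is not None else v

    def choice(self, a, size=None, replace=True):
        v = self._ints.pop(0)
        return np.asarray(v)


class TestOperators:
    def test_single_group_initialization_is_all_zero(self):
        rng = np.random.default_rng(0)
        cfg = GAConfig(population_size=5, n_groups=1)
        pop = initialize_population(7, cfg, rng)
        assert all(np.all(c.labels == 0) for c in pop)

    def test_initialization_is_uniform(self):
        rng = np.random.default_rng(1)
        cfg = GAConfig(population_size=1000, n_groups=3)
        pop = initialize_population(100, cfg, rng)
        labels = np.concatenate([c.labels for c in pop])
        n = labels.size
        for g in range(3):
            freq = (labels == g).mean()
            sigma = np.sqrt((1 / 3) * (2 / 3) / n)
            assert abs(freq - 1 / 3) < 3 * sigma + 1e-9

    def test_same_seed_same_population(self):
        cfg = GAConfig(population_size=10, n_groups=3)
        p1 = initialize_population(20, cfg, np.random.default_rng(42))
        p2 = initialize_population(20, cfg, np.random.default_rng(42))
        assert p1 == p2

    def test_mutate_zero_probability_is_identity(self):
        c = Chromosome([0, 1, 2, 0, 1], 3)
        out = mutate(c, 0.0, np.random.default_rng(0), n_groups=3)
        assert out == c and out is not c

    def test_mutate_resampling_includes_current_label(self):
        # with p=1 and g groups the changed fraction tends to (g-1)/g
        rng = np.random.default_rng(2)
        c = Chromosome(np.zeros(10_000, dtype=int), 3)
        out = mutate(c, 1.0, rng, n_groups=3)
        changed = (out.labels != c.labels).mean()
        assert abs(changed - 2 / 3) < 0.02

    def test_mutate_labels_stay_in_range(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c = Chromosome(rng.integers(0, 4, size=30), 4)
            out = mutate(c, 0.5, rng, n_groups=4)
            assert out.labels.min() >= 0 and out.labels.max() < 4

    def test_single_crossover_with_forced_cut(self):
        a = Chromosome([0, 0, 0, 0])
        b = Chromosome([1, 1, 1, 1])
        ca, cb = crossover(a, b, "single", FakeRNG(integers=[2]))
        assert ca.labels.tolist() == [0, 0, 1, 1]
        assert cb.labels.tolist() == [1, 1, 0, 0]

    def test_double_crossover_swaps_middle_segment(self):
        a = Chromosome([0, 0, 0, 0, 0])
        b = Chromosome([1, 1, 1, 1, 1])
        ca, cb = crossover(a, b, "double", FakeRNG(integers=[[1, 3]]))
        assert ca.labels.tolist() == [0, 1, 1, 0, 0]
        assert cb.labels.tolist() == [1, 0, 0, 1, 1]

    def test_identical_parents_give_identical_children(self):
        a = Chromosome([0, 1, 2, 1, 0])
        for mode in ("single", "double"):
            ca, cb = crossover(a, a, mode, np.random.default_rng(3))
            assert ca == a and cb == a

    def test_crossover_conserves_positionwise_alleles(self):
        rng = np.random.default_rng(4)
        for mode in ("single", "double"):
            a = Chromosome(rng.integers(0, 3, size=30), 3)
            b = Chromosome(rng.integers(0, 3, size=30), 3)
            ca, cb = crossover(a, b, mode, rng)
            for i in range(30):
                assert sorted([ca.labels[i], cb.labels[i]]) == sorted([a.labels[i], b.labels[i]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossover(Chromosome([0, 1]), Chromosome([0, 1, 2]), "single",
                      np.random.default_rng(0))


class TestGroupScore:
    def test_single_term_projection(self):
        w = FitnessWeights(0.0, 0.0, 1.0, 0.0, 0.0, 0.0)
        st = make_stats(cc_anom=0.37)
        assert group_score(st, w) == pytest.approx(0.37)

    def test_higher_r_meas_lowers_score(self):
        w = FitnessWeights()
        lo = group_score(make_stats(r_meas_inner=0.1), w)
        hi = group_score(make_stats(r_meas_inner=0.3), w)
        assert hi < lo

    def test_r_meas_enters_through_inner_shell_only(self):
        w = FitnessWeights()
        a = group_score(make_stats(r_meas_inner=0.1, r_meas_overall=0.9), w)
        b = group_score(make_stats(r_meas_inner=0.1, r_meas_overall=0.2), w)
        assert a == pytest.approx(b)
        c = group_score(make_stats(r_meas_inner=0.5, r_meas_overall=0.2), w)
        assert c < a

    def test_missing_statistic_with_weight_is_penalised(self):
        w = FitnessWeights()
        st = make_stats()
        missing = MergingStats(**{
            **{n: getattr(st, n) for n in (
                "r_merge", "r_meas", "cc_half", "cc_anom", "sig_ano",
                "completeness", "multiplicity")},
            "i_over_sigma": ShellTriple(None, None, None),
        })
        assert group_score(missing, w, penalty=1000.0) < group_score(st, w) - 900


class TestChromosomeFitness:
    def test_single_group_chromosome_equals_group_score(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(n_groups=2, seed=3)
        fit, best, stats = chromosome_fitness(
            np.zeros(pool.n_subdatasets, dtype=int), pool, FitnessWeights(), cfg
        )
        assert best == 0
        assert fit == pytest.approx(group_score(stats[0], FitnessWeights()))

    def test_label_permutation_symmetry(self, small_pool):
        pool, _ = small_pool
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 3, size=pool.n_subdatasets)
        cfg = GAConfig(n_groups=3, seed=5)
        f1, _, _ = chromosome_fitness(labels, pool, FitnessWeights(), cfg)
        f2, _, _ = chromosome_fitness((labels + 1) % 3, pool, FitnessWeights(), cfg)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_no_qualifying_group_gets_penalty(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(n_groups=pool.n_subdatasets, min_group_size=3, seed=0)
        labels = np.arange(pool.n_subdatasets)  # every group a singleton
        fit, best, stats = chromosome_fitness(labels, pool, FitnessWeights(), cfg)
        assert best is None and stats == {} and fit < -1000

    def test_true_split_beats_all_in_one_under_strong_nonisomorphism(self):
        # balanced weights keep any one statistic from dominating; the split
        # chromosome's best group is then a pure class with much lower R_meas
        wins = 0
        for seed in range(60, 70):
            pool, truth = gm.make_pool(small_synthetic_config(seed=seed, junk=0))
            cfg = GAConfig(n_groups=2, seed=seed)
            w = balance_weights(pool, cfg, r_user=0.1,
                                user_multipliers={"multiplicity": 0.0})
            cls = truth.class_of_subdataset
            split = np.array([0 if cls[s] == "A" else 1 for s in pool.ids])
            f_split, _, _ = chromosome_fitness(split, pool, w, cfg)
            f_one, _, _ = chromosome_fitness(np.zeros_like(split), pool, w, cfg)
            wins += f_split >= f_one
        assert wins >= 8


class TestBalanceWeights:
    def test_defining_property_and_linearity(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=20, seed=9, n_groups=3)
        w1 = balance_weights(pool, cfg, r_user=1.0)
        report = w1.balance_report
        for term in ("i_over_sigma", "cc_anom", "cc_half", "completeness", "multiplicity"):
            best = report["best_terms"][term]
            if term in report["zeroed"]:
                assert getattr(w1, f"w_{term}") == 0.0
            else:
                assert best * getattr(w1, f"w_{term}") == pytest.approx(1.0, abs=1e-12)
        w2 = balance_weights(pool, cfg, r_user=2.0)
        for term in ("i_over_sigma", "cc_anom", "cc_half", "completeness", "multiplicity"):
            assert getattr(w2, f"w_{term}") == pytest.approx(2 * getattr(w1, f"w_{term}"), rel=1e-15)
        assert w1.w_r_meas == w2.w_r_meas == 1.0

    def test_user_multipliers_are_applied_on_top(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=10, seed=9, n_groups=3)
        w = balance_weights(pool, cfg, r_user=1.0, user_multipliers={"cc_anom": 4.0})
        assert w.effective("cc_anom") == pytest.approx(4.0 * w.w_cc_anom)

    def test_rejects_nonpositive_r_user(self, small_pool):
        pool, _ = small_pool
        with pytest.raises(ValueError):
            balance_weights(pool, GAConfig(seed=0), r_user=0.0)


class TestEvolve:
    def test_archive_bookkeeping(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=2, generations=1, seed=0, n_groups=2)
        res = evolve(pool, FitnessWeights(), cfg)
        assert len(res.archive) == 2

    def test_archive_size_is_population_times_generations(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=8, generations=5, seed=1, n_groups=2)
        res = evolve(pool, FitnessWeights(), cfg)
        assert len(res.archive) == 40

    def test_best_ever_fitness_is_monotone(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=10, generations=15, seed=2, n_groups=3)
        res = evolve(pool, FitnessWeights(), cfg)
        running = np.maximum.accumulate(res.generations_best)
        assert np.all(np.diff(running) >= 0)
        # with elitism the per-generation best never drops below the running best
        assert np.allclose(res.generations_best, running)

    def test_best_fitness_matches_archive_maximum(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=10, generations=10, seed=3, n_groups=3)
        res = evolve(pool, FitnessWeights(), cfg)
        assert res.best_fitness == pytest.approx(res.archive.fitness_values.max())

    def test_bit_identical_determinism(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=10, generations=8, seed=7, n_groups=3)
        r1 = evolve(pool, FitnessWeights(), cfg)
        r2 = evolve(pool, FitnessWeights(), cfg)
        assert np.array_equal(r1.best_chromosome.labels, r2.best_chromosome.labels)
        assert r1.best_fitness == r2.best_fitness
        assert np.array_equal(r1.archive.fitness_values, r2.archive.fitness_values)


class TestRandomControl:
    def test_budget(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=6, generations=7, seed=4, n_groups=3)
        archive = random_control(pool, FitnessWeights(), cfg)
        assert len(archive) == 42

    def test_control_explores_more_diversely_than_converged_ga(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=15, generations=20, seed=5, n_groups=3)
        res = evolve(pool, FitnessWeights(), cfg)
        control = random_control(pool, FitnessWeights(), cfg)
        last_gen = [r.fitness for r in res.archive if r.generation == 19]
        assert np.var(control.fitness_values) > np.var(last_gen)


class TestExhaustiveOracle:
    def test_enumeration_count_up_to_label_symmetry(self):
        assert sum(1 for _ in _restricted_growth_strings(3, 2)) == 4

    def test_refuses_large_spaces(self, small_pool):
        pool, _ = small_pool
        with pytest.raises(ValueError, match="exceeds"):
            exhaustive_oracle(pool, FitnessWeights(), GAConfig(n_groups=4, seed=0),
                              limit=1000)

    def test_oracle_dominates_random_probes(self):
        pool, truth = gm.make_pool(small_synthetic_config(seed=21, n_per_class=3, junk=0,
                                                          n_unique=120))
        cfg = GAConfig(n_groups=2, seed=21)
        w = FitnessWeights()
        best, f_best = exhaustive_oracle(pool, w, cfg)
        rng = np.random.default_rng(0)
        for _ in range(100):
            labels = rng.integers(0, 2, size=pool.n_subdatasets)
            f, _, _ = chromosome_fitness(labels, pool, w, cfg)
            assert f <= f_best + 1e-12

    def test_planted_partition_recovered_exactly(self):
        # noise-free non-isomorphous classes: the optimum is one pure class
        cfg_s = small_synthetic_config(seed=22, n_per_class=4, junk=0, n_unique=150,
                                       noise_scale=0.05)
        pool, truth = gm.make_pool(cfg_s)
        cfg = GAConfig(n_groups=2, seed=22)
        w = balance_weights(pool, cfg, r_user=0.1, user_multipliers={"multiplicity": 0.0})
        best, _ = exhaustive_oracle(pool, w, cfg)
        cls = truth.class_of_subdataset
        groups = {}
        for lab, sid in zip(best.labels, pool.ids):
            groups.setdefault(int(lab), set()).add(cls[sid])
        # at least one group is a pure planted class
        assert any(v == {"A"} or v == {"B"} for v in groups.values())

    def test_evolve_reaches_oracle_optimum_on_small_pools(self):
        hits = 0
        for seed in (31, 32, 33, 34, 35):
            pool, _ = gm.make_pool(small_synthetic_config(seed=seed, n_per_class=3, junk=0,
                                                          n_unique=120))
            cfg = GAConfig(population_size=30, generations=40, n_groups=2, seed=seed)
            w = FitnessWeights()
            res = evolve(pool, w, cfg)
            _, f_oracle = exhaustive_oracle(pool, w, cfg)
            hits += abs(res.best_fitness - f_oracle) < 1e-9
        assert hits >= 4


class TestArchiveSerialization:
    def test_frame_round_trip(self, small_pool):
        pool, _ = small_pool
        cfg = GAConfig(population_size=6, generations=4, seed=12, n_groups=3)
        res = evolve(pool, FitnessWeights(), cfg)
        frame = res.archive.to_frame()
        back = gm.Archive.from_frame(frame)
        assert len(back) == len(res.archive)
        for a, b in zip(res.archive, back):
            assert a.generation == b.generation
            assert np.array_equal(a.labels, b.labels)
            assert a.fitness == pytest.approx(b.fitness)
            assert a.best_group == b.best_group
            assert set(a.group_stats) == set(b.group_stats)
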