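"""GA operator contracts: seeding, reproduction composition, elitism."""

import numpy as np
import pytest

from skinspace import (
    ComponentSubset,
    GaConfig,
    PlantedMatrixConfig,
    evaluate_fitness,
    init_population,
    next_generation,
    planted_matrix,
    run_ga,
)
from skinspace.ga import FitnessRecord

FAST = dict(cv_folds=3, fitness_trees=5, fitness_subsample=2000)


def _records(population, f_scores):
    return [
        FitnessRecord(subset=s, f_score=f, error_rate=1.0 - f)
        for s, f in zip(population, f_scores)
    ]


class TestInitPopulation:
    def test_default_size_25(self):
        assert len(init_population(GaConfig(seed=0))) == 25

    def test_same_seed_identical(self):
        a = init_population(GaConfig(seed=42))
        b = init_population(GaConfig(seed=42))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.mask, sb.mask)

    def test_all_nonempty(self):
        for seed in range(5):
            for subset in init_population(GaConfig(seed=seed)):
                assert subset.mask.any()

    def test_small_population_rejected(self):
        with pytest.raises(ValueError, match="population_size"):
            GaConfig(population_size=1)


class TestComponentSubset:
    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ComponentSubset(np.zeros(8, dtype=bool))

    def test_key_distinguishes(self):
        a = np.zeros(8, dtype=bool)
        a[0] = True
        b = np.zeros(8, dtype=bool)
        b[1] = True
        assert ComponentSubset(a).key() != ComponentSubset(b).key()


class TestEvaluateFitness:
    def test_perfect_separator_column(self):
        rng = np.random.default_rng(0)
        n = 400
        labels = rng.integers(0, 2, size=n).astype(np.uint8)
        values = rng.normal(size=(n, 5))
        values[:, 2] = labels  # the designated column equals the label
        from skinspace import PixelFeatureMatrix

        data = PixelFeatureMatrix(values, labels, tuple(f"c{i}" for i in range(5)))
        mask = np.zeros(5, dtype=bool)
        mask[2] = True
        rec = evaluate_fitness(ComponentSubset(mask), data, GaConfig(seed=0, **FAST))
        assert rec.f_score == 1.0

    def test_noise_columns_chance_band(self):
        from skinspace import PixelFeatureMatrix

        scores = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 400
            labels = (np.arange(n) % 2).astype(np.uint8)
            values = rng.normal(size=(n, 4))
            data = PixelFeatureMatrix(values, labels, ("a", "b", "c", "d"))
            rec = evaluate_fitness(
                ComponentSubset(np.ones(4, dtype=bool)), data, GaConfig(seed=seed, **FAST)
            )
            scores.append(rec.f_score)
        assert all(0.35 <= s <= 0.65 for s in scores), scores

    def test_single_class_rejected(self):
        from skinspace import PixelFeatureMatrix

        data = PixelFeatureMatrix(
            np.random.default_rng(0).normal(size=(50, 3)),
            np.ones(50, dtype=np.uint8),
            ("a", "b", "c"),
        )
        with pytest.raises(ValueError, match="both classes"):
            evaluate_fitness(
                ComponentSubset(np.ones(3, dtype=bool)), data, GaConfig(seed=0, **FAST)
            )


class TestNextGeneration:
    def test_pure_elitism_preserves_best(self):
        config = GaConfig(
            seed=0,
            population_size=4,
            mutation_prob=0.0,
            crossover_prob=0.0,
            model_sample_fraction=0.0,
            random_fraction=0.0,
        )
        rng = np.random.default_rng(0)
        population = init_population(config, 10)
        records = _records(population, [0.1, 0.9, 0.2, 0.3])
        new = next_generation(records, config, rng)
        np.testing.assert_array_equal(new[0].mask, population[1].mask)

    def test_population_size_conserved(self):
        config = GaConfig(seed=1)
        rng = np.random.default_rng(1)
        population = init_population(config, 32)
        records = _records(population, list(np.linspace(0.2, 0.8, 25)))
        assert len(next_generation(records, config, rng)) == 25

    def test_model_samples_inherit_unanimous_bit(self):
        # all individuals share bit 3 -> elite marginal is 1 there
        config = GaConfig(seed=0, mutation_prob=0.0)
        rng = np.random.default_rng(0)
        masks = []
        gen = np.random.default_rng(99)
        for _ in range(25):
            m = gen.random(12) < 0.5
            m[3] = True
            masks.append(ComponentSubset(m))
        records = _records(masks, list(np.linspace(0.9, 0.5, 25)))
        new = next_generation(records, config, rng)
        n_model = int(round(config.model_sample_fraction * 25))
        for child in new[1 : 1 + n_model]:
            assert child.mask[3]

    def test_mismatched_lengths_rejected(self):
        config = GaConfig(seed=0)
        records = _records(init_population(config, 8), [0.5] * 25)
        with pytest.raises(ValueError, match="records"):
            next_generation(records[:-1], config, np.random.default_rng(0))

    def test_all_genomes_nonempty_and_sized(self):
        config = GaConfig(seed=3, mutation_prob=0.3)
        rng = np.random.default_rng(3)
        population = init_population(config, 16)
        records = _records(population, list(np.linspace(0.1, 0.9, 25)))
        for _ in range(5):
            population = next_generation(records, config, rng)
            for s in population:
                assert s.mask.size == 16 and s.mask.any()
            records = _records(population, list(np.linspace(0.1, 0.9, 25)))


class TestRunGa:
    def test_history_best_non_decreasing_and_deterministic(self):
        data = planted_matrix(PlantedMatrixConfig(n=300, m=8, informative=(1,), seed=5))
        config = GaConfig(seed=5, max_generations=6, stall_window=3, **FAST)
        a = run_ga(data, config)
        b = run_ga(data, config)
        bests = [h["best_f"] for h in a.history]
        assert all(y >= x for x, y in zip(bests, bests[1:]))
        assert [h["best_f"] for h in b.history] == bests
        np.testing.assert_array_equal(a.best.subset.mask, b.best.subset.mask)

    def test_single_generation_bound(self):
        data = planted_matrix(PlantedMatrixConfig(n=200, m=6, informative=(0,), seed=2))
        result = run_ga(data, GaConfig(seed=2, max_generations=1, stall_window=1, **FAST))
        assert result.n_generations == 1

    def test_planted_beats_noise(self):
        # median fitness of the true subset >= any pure-noise subset
        planted_scores, noise_scores = [], []
        for seed in range(5):
            data = planted_matrix(
                PlantedMatrixConfig(n=500, m=10, informative=(0, 1), separation=4, seed=seed)
            )
            config = GaConfig(seed=seed, **FAST)
            good = np.zeros(10, dtype=bool)
            good[:2] = True
            bad = np.zeros(10, dtype=bool)
            bad[5:8] = True
            planted_scores.append(
                evaluate_fitness(ComponentSubset(good), data, config).f_score
            )
            noise_scores.append(
                evaluate_fitness(ComponentSubset(bad), data, config).f_score
            )
        assert np.median(planted_scores) >= np.median(noise_scores)
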