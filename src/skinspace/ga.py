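"""Wrapper feature selection over the component registry.

A genetic algorithm searches boolean component subsets; fitness is the
cross-validated skin-class F-score of a small random forest trained on the
selected columns.  Reproduction follows an estimation-of-distribution
pattern: besides elitism, crossover and mutation, part of each generation is
sampled from a univariate marginal model fit to the fittest individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .colorspaces import PixelFeatureMatrix

__all__ = [
    "ComponentSubset",
    "GaConfig",
    "FitnessRecord",
    "GaResult",
    "init_population",
    "evaluate_fitness",
    "next_generation",
    "run_ga",
]


@dataclass(frozen=True)
class ComponentSubset:
    """Boolean inclusion mask over registry entries (a GA genome)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 1:
            raise ValueError("mask must be 1-D")
        if not mask.any():
            raise ValueError("subset must include at least one component")
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def key(self) -> bytes:
        return np.packbits(self.mask).tobytes()


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 25
    mutation_prob: float = 0.035
    crossover_prob: float = 0.55
    max_generations: int = 500
    stall_window: int = 100
    elite_fraction: float = 0.4
    model_sample_fraction: float = 0.5
    random_fraction: float = 0.2
    cv_folds: int = 10
    fitness_subsample: int = 20_000
    fitness_trees: int = 15
    target_fitness: float = 1.0  # F is bounded by 1: stop once unbeatable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("mutation_prob", "crossover_prob", "elite_fraction",
                     "model_sample_fraction", "random_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        # one slot is reserved for the carried-over best individual
        if self.model_sample_fraction + self.random_fraction + 1.0 / self.population_size > 1.0 + 1e-9:
            raise ValueError("model/random fractions plus elite slot exceed the population")
        if self.max_generations < 1 or self.stall_window < 1:
            raise ValueError("max_generations and stall_window must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class FitnessRecord:
    subset: ComponentSubset
    f_score: float
    error_rate: float
    generation: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_score <= 1.0:
            raise ValueError("f_score must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")


@dataclass(frozen=True)
class GaResult:
    best: FitnessRecord
    history: tuple[dict, ...]  # per generation: best_f, mean_f, error_rate

    @property
    def n_generations(self) -> int:
        return len(self.history)


def _random_subset(rng: np.random.Generator, m: int) -> ComponentSubset:
    while True:
        mask = rng.random(m) < 0.5
        if mask.any():
            return ComponentSubset(mask)


def init_population(config: GaConfig, n_components: int = 32) -> list[ComponentSubset]:
    """Seeded random population; each bit Bernoulli(0.5), empties resampled."""
    rng = np.random.default_rng(config.seed)
    return [_random_subset(rng, n_components) for _ in range(config.population_size)]


def _stratified_subsample(
    data: PixelFeatureMatrix, limit: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    y = data.labels
    if data.n_pixels <= limit:
        return data.values, y
    idx_parts = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        take = max(1, int(round(limit * cls_idx.size / y.size)))
        idx_parts.append(rng.choice(cls_idx, size=min(take, cls_idx.size), replace=False))
    idx = np.sort(np.concatenate(idx_parts))
    return data.values[idx], y[idx]


def evaluate_fitness(
    subset: ComponentSubset,
    data: PixelFeatureMatrix | tuple[np.ndarray, np.ndarray],
    config: GaConfig,
    generation: int = 0,
) -> FitnessRecord:
    """Cross-validated skin-class F-score of the fitness classifier.

    ``data`` may be a feature matrix (subsampled here per config) or a
    pre-subsampled ``(X, y)`` tuple as drawn once by :func:`run_ga`.
    """
    if isinstance(data, PixelFeatureMatrix):
        rng = np.random.default_rng(config.seed)
        X_all, y = _stratified_subsample(data, config.fitness_subsample, rng)
    else:
        X_all, y = data
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("fitness data must contain both classes")
    X = X_all[:, subset.indices()]
    folds = min(config.cv_folds, int(np.bincount(y.astype(int)).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    f_scores, errors = [], []
    for train_idx, test_idx in skf.split(X, y):
        clf = RandomForestClassifier(
            n_estimators=config.fitness_trees, random_state=config.seed, n_jobs=1
        )
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        f_scores.append(f1_score(y[test_idx], pred, pos_label=1, zero_division=0.0))
        errors.append(float(np.mean(pred != y[test_idx])))
    return FitnessRecord(
        subset=subset,
        f_score=float(np.mean(f_scores)),
        error_rate=float(np.mean(errors)),
        generation=generation,
    )


def _mutate(mask: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    if prob <= 0.0:
        return mask
    flips = rng.random(mask.size) < prob
    return mask ^ flips


def _nonempty(mask: np.ndarray, rng: np.random.Generator) -> ComponentSubset:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return ComponentSubset(mask)


def next_generation(
    records: Sequence[FitnessRecord], config: GaConfig, rng: np.random.Generator
) -> list[ComponentSubset]:
    """Produce the next population from evaluated fitness records.

    Composition: 1 elite (best genome, unchanged) + model samples from the
    univariate marginal of the top ``elite_fraction`` individuals + fresh
    random genomes + fitness-proportional crossover/mutation offspring.
    """
    if not records:
        raise ValueError("records must be non-empty")
    pop = config.population_size
    if len(records) != pop:
        raise ValueError(f"expected {pop} fitness records, got {len(records)}")
    m = records[0].subset.mask.size
    ranked = sorted(records, key=lambda r: r.f_score, reverse=True)

    n_model = int(round(config.model_sample_fraction * pop))
    n_random = int(round(config.random_fraction * pop))
    n_cross = pop - 1 - n_model - n_random
    if n_cross < 0:  # rounding pushed us over; shrink the model share
        n_model += n_cross
        n_cross = 0

    out: list[ComponentSubset] = [ComponentSubset(ranked[0].subset.mask.copy())]

    # univariate marginal model over the elite set
    n_elite = max(1, int(np.ceil(config.elite_fraction * pop)))
    elite_masks = np.stack([r.subset.mask for r in ranked[:n_elite]])
    marginal = elite_masks.mean(axis=0)
    for _ in range(n_model):
        out.append(_nonempty(rng.random(m) < marginal, rng))

    for _ in range(n_random):
        out.append(_random_subset(rng, m))

    weights = np.array([r.f_score for r in records], dtype=float) + 1e-9
    weights /= weights.sum()
    for _ in range(n_cross):
        i, j = rng.choice(len(records), size=2, p=weights)
        pa, pb = records[i].subset.mask, records[j].subset.mask
        if rng.random() < config.crossover_prob:
            take = rng.random(m) < 0.5
            child = np.where(take, pa, pb)
        else:
            child = pa.copy()
        child = _mutate(child, config.mutation_prob, rng)
        out.append(_nonempty(np.asarray(child, dtype=bool), rng))
    return out


def run_ga(
    data: PixelFeatureMatrix,
    config: GaConfig | None = None,
) -> GaResult:
    """Run the generational loop until the cap or a fitness plateau.

    The fitness subsample is drawn once so every candidate in the run sees
    identical data; per-genome fitness is cached (the same subset is never
    re-evaluated).  The best-ever record is returned with a per-generation
    history whose best-fitness column is non-decreasing by construction.
    """
    config = config or GaConfig()
    rng = np.random.default_rng(config.seed)
    sub_rng = np.random.default_rng(config.seed)
    X_y = _stratified_subsample(data, config.fitness_subsample, sub_rng)

    cache: dict[bytes, FitnessRecord] = {}

    def fitness(subset: ComponentSubset, gen: int) -> FitnessRecord:
        key = subset.key()
        if key not in cache:
            cache[key] = evaluate_fitness(subset, X_y, config, generation=gen)
        return replace(cache[key], subset=subset, generation=gen)

    population = init_population(config, data.n_components)
    best: FitnessRecord | None = None
    history: list[dict] = []
    stall = 0
    for gen in range(1, config.max_generations + 1):
        records = [fitness(s, gen) for s in population]
        gen_best = max(records, key=lambda r: r.f_score)
        if best is None or gen_best.f_score > best.f_score + 1e-12:
            best = gen_best
            stall = 0
        else:
            stall += 1
        history.append(
            {
                "generation": gen,
                "best_f": best.f_score,
                "mean_f": float(np.mean([r.f_score for r in records])),
                "error_rate": best.error_rate,
            }
        )
        if (
            gen >= config.max_generations
            or stall >= config.stall_window
            or best.f_score >= config.target_fitness
        ):
            break
        population = next_generation(records, config, rng)
    assert best is not None
    return GaResult(best=best, history=tuple(history))
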