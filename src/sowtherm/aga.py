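"""Adaptive genetic algorithm (AGA) tuning of forest hyperparameters.

A plain generational GA — roulette selection, single-point crossover,
uniform gene resampling, elitism — whose crossover and mutation rates adapt
to fitness.  With f_max the population maximum, f̄ the population mean, f′
the fitter of a crossover pair and f the fitness of the individual being
mutated (k1..k4 constants in [0, 1]):

    Pc = k1 · (f_max − f′) / (f_max − f̄)   if f′ ≥ f̄,   else k2
    Pm = k3 · (f_max − f)  / (f_max − f̄)   if f  ≥ f̄,   else k4

so the fittest individuals are crossed and mutated least (their genes are
preserved) while below-average individuals get the constant exploratory
rates.  A degenerate population (f_max − f̄ below ``eps``) also falls back
to the exploratory constants, since the ratio is then 0/0.

Fitness of a genome is 1 / (1 + MSE_cv): the k-fold cross-validated mean
squared error of a forest built with that genome's hyperparameters, mapped
to (0, 1] so that roulette selection and the adaptive ratios above are
well defined.

``fit_aga_rf`` runs the search and refits the best genome on the full
training data — the AGA-RF regressor.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .forest import ForestHyperparams, ForestModel, fit_forest
from .metrics import mse

__all__ = [
    "GeneSpec",
    "SearchSpace",
    "AGAConfig",
    "default_search_space",
    "compact_search_space",
    "crossover_probability",
    "mutation_probability",
    "fitness_from_mse",
    "evaluate_fitness",
    "evolve",
    "fit_aga_rf",
]


@dataclass(frozen=True)
class GeneSpec:
    """One gene: a named, finite grid of admissible values."""

    name: str
    values: tuple

    def __post_init__(self):
        if len(self.values) < 1:
            raise ConfigurationError(f"gene {self.name!r} has no values")
        object.__setattr__(self, "values", tuple(self.values))

    @classmethod
    def integer_range(cls, name: str, low: int, high: int, step: int = 1):
        if high < low or step < 1:
            raise ConfigurationError(
                f"gene {name!r}: invalid integer range {low}..{high} step {step}")
        return cls(name, tuple(range(low, high + 1, step)))


@dataclass(frozen=True)
class SearchSpace:
    """Ordered gene grid; genomes are tuples aligned with ``genes``."""

    genes: tuple

    def __post_init__(self):
        if len(self.genes) < 1:
            raise ConfigurationError("search space must have at least one gene")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate gene names: {names}")
        object.__setattr__(self, "genes", tuple(self.genes))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def size(self) -> int:
        out = 1
        for g in self.genes:
            out *= len(g.values)
        return out

    def contains(self, genome: tuple) -> bool:
        return (len(genome) == self.n_genes
                and all(v in g.values for v, g in zip(genome, self.genes)))

    def random_genome(self, rng: np.random.Generator) -> tuple:
        return tuple(g.values[rng.integers(0, len(g.values))]
                     for g in self.genes)

    def all_genomes(self):
        """Exhaustive enumeration (for brute-force oracles on small spaces)."""
        import itertools

        return itertools.product(*(g.values for g in self.genes))

    def to_hyperparams(self, genome: tuple) -> ForestHyperparams:
        if not self.contains(genome):
            raise ConfigurationError(
                f"genome {genome} outside the search space")
        kwargs = dict(zip((g.name for g in self.genes), genome))
        return ForestHyperparams(**kwargs)

    def genome_dict(self, genome: tuple) -> dict:
        return dict(zip((g.name for g in self.genes), genome))


def default_search_space() -> SearchSpace:
    """The broad default grid over all four forest hyperparameters."""
    return SearchSpace((
        GeneSpec.integer_range("n_trees", 50, 500, 50),
        GeneSpec.integer_range("max_depth", 3, 20),
        GeneSpec.integer_range("min_samples_leaf", 1, 10),
        GeneSpec("max_features", (0.3, 0.5, 0.7, 1.0)),
    ))


def compact_search_space() -> SearchSpace:
    """A small grid for desk-scale experiments and quick tuning runs."""
    return SearchSpace((
        GeneSpec("n_trees", (25, 50, 100)),
        GeneSpec("max_depth", (4, 8, 12, 16)),
        GeneSpec("min_samples_leaf", (1, 2, 4, 8)),
        GeneSpec("max_features", (0.5, 0.75, 1.0)),
    ))


@dataclass(frozen=True)
class AGAConfig:
    population_size: int = 20
    generations: int = 30
    k1: float = 0.9
    k2: float = 0.9
    k3: float = 0.1
    k4: float = 0.1
    elitism_count: int = 1
    cv_folds: int = 3
    seed: int = 0
    eps: float = 1e-12

    def validate(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.population_size < 2:
            raise ConfigurationError(
                f"population_size must be >= 2, got {self.population_size}")
        if not 0 <= self.elitism_count < self.population_size:
            raise ConfigurationError(
                f"elitism_count must lie in [0, population_size), "
                f"got {self.elitism_count}")
        if self.generations < 0:
            raise ConfigurationError(
                f"generations must be >= 0, got {self.generations}")
        if self.cv_folds < 2:
            raise ConfigurationError(
                f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.eps <= 0:
            raise ConfigurationError(f"eps must be > 0, got {self.eps}")


def _check_adaptive_args(f_ind, f_max, f_avg, ka, kb) -> None:
    for name, v in (("k_adaptive", ka), ("k_constant", kb)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    if f_max < f_avg:
        raise DomainError(f"f_max ({f_max}) must be >= f_avg ({f_avg})")
    if f_ind > f_max:
        raise DomainError(
            f"individual fitness ({f_ind}) cannot exceed f_max ({f_max})")


def crossover_probability(f_prime: float, f_max: float, f_avg: float,
                          k1: float, k2: float, eps: float = 1e-12) -> float:
    """Adaptive crossover rate Pc for a pair whose better fitness is f′.

    f′ ≥ f̄ takes the adaptive branch k1·(f_max−f′)/(f_max−f̄) — including
    the boundary f′ = f̄ exactly; f′ < f̄ returns the constant k2; a
    degenerate population (f_max − f̄ < eps) returns k2.
    """
    _check_adaptive_args(f_prime, f_max, f_avg, k1, k2)
    if f_max - f_avg < eps:
        return k2
    if f_prime < f_avg:
        return k2
    return k1 * (f_max - f_prime) / (f_max - f_avg)


def mutation_probability(f: float, f_max: float, f_avg: float,
                         k3: float, k4: float, eps: float = 1e-12) -> float:
    """Adaptive per-gene mutation rate Pm for an individual of fitness f."""
    _check_adaptive_args(f, f_max, f_avg, k3, k4)
    if f_max - f_avg < eps:
        return k4
    if f < f_avg:
        return k4
    return k3 * (f_max - f) / (f_max - f_avg)


def fitness_from_mse(mse_cv: float) -> float:
    """Map a cross-validated MSE to the GA fitness scale, 1/(1 + MSE).

    Positive and bounded in (0, 1] — both required: roulette selection
    needs nonnegative weights and the adaptive Pc/Pm ratios need a
    meaningful population maximum.
    """
    if mse_cv < 0:
        raise DomainError(f"MSE cannot be negative, got {mse_cv}")
    return 1.0 / (1.0 + mse_cv)


def _genome_seed(seed: int, genome: tuple) -> int:
    digest = zlib.crc32(repr(genome).encode()) & 0x7FFFFFFF
    return (int(seed) ^ digest) & 0x7FFFFFFF


def evaluate_fitness(genome: tuple, X, y, space: SearchSpace,
                     cv_folds: int = 3, seed: int = 0) -> float:
    """Cross-validated fitness 1/(1 + MSE_cv) of one genome, in (0, 1].

    Fold assignment depends on ``seed`` only (all genomes see the same
    folds); the per-fold forest seed mixes in a genome digest so repeated
    evaluations are deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if cv_folds > n:
        raise ConfigurationError(
            f"cv_folds ({cv_folds}) exceeds the number of samples ({n})")
    params = space.to_hyperparams(genome)
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, cv_folds)
    gseed = _genome_seed(seed, genome)
    fold_mse = []
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        model = fit_forest(X[train_mask], y[train_mask], params,
                           seed=(gseed + k) & 0x7FFFFFFF)
        fold_mse.append(mse(y[test_idx], model.predict(X[test_idx])))
    return fitness_from_mse(float(np.mean(fold_mse)))


@dataclass
class _Individual:
    genome: tuple
    fitness: float | None = None
    ref_fitness: float | None = None  # fitness basis for Pm (pre-evaluation)


def _roulette(rng: np.random.Generator, fitnesses: np.ndarray) -> int:
    total = fitnesses.sum()
    if total <= 0:
        return int(rng.integers(0, fitnesses.size))
    return int(rng.choice(fitnesses.size, p=fitnesses / total))


def evolve(space: SearchSpace, X=None, y=None, config: AGAConfig | None = None,
           fitness_fn=None) -> tuple[tuple, list[dict]]:
    """Run the adaptive GA; return (best genome ever seen, history).

    ``fitness_fn(genome) -> float`` overrides the cross-validated fitness
    (used with deterministic landscapes in experiments and oracles); when
    absent, X and y are required.  History holds one dict per evaluated
    generation: f_max, f_avg, best-so-far fitness.  With elitism ≥ 1 the
    best-so-far trajectory is non-decreasing.
    """
    config = config or AGAConfig()
    config.validate()
    if fitness_fn is None:
        if X is None or y is None:
            raise ConfigurationError("evolve needs (X, y) or a fitness_fn")
        cache: dict[tuple, float] = {}

        def fitness_fn(genome, _cache=cache):
            if genome not in _cache:
                _cache[genome] = evaluate_fitness(
                    genome, X, y, space, cv_folds=config.cv_folds,
                    seed=config.seed)
            return _cache[genome]

    rng = np.random.default_rng(config.seed)
    pop = [_Individual(space.random_genome(rng))
           for _ in range(config.population_size)]
    for ind in pop:
        ind.fitness = float(fitness_fn(ind.genome))

    best_genome = max(pop, key=lambda i: i.fitness).genome
    best_fitness = max(i.fitness for i in pop)
    history = []

    def record():
        fits = np.array([i.fitness for i in pop])
        f_max = float(fits.max())
        history.append({"f_max": f_max,
                        "f_avg": min(float(fits.mean()), f_max),
                        "best_so_far": float(best_fitness)})

    record()

    for _gen in range(config.generations):
        fits = np.array([i.fitness for i in pop])
        f_max = float(fits.max())
        # mean can exceed max by 1 ulp on a uniform population; clamp to
        # keep the adaptive-rate domain (f_max >= f_avg) valid
        f_avg = min(float(fits.mean()), f_max)

        elite_order = sorted(range(len(pop)), key=lambda i: -pop[i].fitness)
        nxt: list[_Individual] = [
            _Individual(pop[i].genome, fitness=pop[i].fitness,
                        ref_fitness=pop[i].fitness)
            for i in elite_order[:config.elitism_count]
        ]

        while len(nxt) < config.population_size:
            pa = pop[_roulette(rng, fits)]
            pb = pop[_roulette(rng, fits)]
            f_prime = max(pa.fitness, pb.fitness)
            pc = crossover_probability(f_prime, f_max, f_avg,
                                       config.k1, config.k2, config.eps)
            if rng.random() < pc and space.n_genes > 1:
                cut = int(rng.integers(1, space.n_genes))
                child_a = pa.genome[:cut] + pb.genome[cut:]
                child_b = pb.genome[:cut] + pa.genome[cut:]
                children = [_Individual(child_a, ref_fitness=f_prime),
                            _Individual(child_b, ref_fitness=f_prime)]
            else:
                children = [_Individual(pa.genome, fitness=pa.fitness,
                                        ref_fitness=pa.fitness),
                            _Individual(pb.genome, fitness=pb.fitness,
                                        ref_fitness=pb.fitness)]
            for child in children:
                pm = mutation_probability(child.ref_fitness, f_max, f_avg,
                                          config.k3, config.k4, config.eps)
                genome = list(child.genome)
                mutated = False
                for gi, gene in enumerate(space.genes):
                    if rng.random() < pm:
                        genome[gi] = gene.values[
                            rng.integers(0, len(gene.values))]
                        mutated = True
                if mutated:
                    child.genome = tuple(genome)
                    child.fitness = None
                nxt.append(child)
        pop = nxt[:config.population_size]

        for ind in pop:
            if ind.fitness is None:
                ind.fitness = float(fitness_fn(ind.genome))
            if ind.fitness > best_fitness:
                best_fitness = ind.fitness
                best_genome = ind.genome
        record()

    return best_genome, history


def fit_aga_rf(X, y, space: SearchSpace | None = None,
               config: AGAConfig | None = None,
               feature_names=None) -> tuple[ForestModel, dict]:
    """AGA-RF: evolve the hyperparameters, refit the winner on all of (X, y).

    Returns the fitted :class:`ForestModel` and a report with the best
    genome, its fitness, the per-generation trajectory, and a config echo.
    """
    space = space or default_search_space()
    config = config or AGAConfig()
    best_genome, history = evolve(space, X, y, config)
    params = space.to_hyperparams(best_genome)
    model = fit_forest(X, y, params,
                       seed=_genome_seed(config.seed, best_genome),
                       feature_names=feature_names)
    report = {
        "best_genome": space.genome_dict(best_genome),
        "best_fitness": history[-1]["best_so_far"],
        "history": history,
        "config": {
            "population_size": config.population_size,
            "generations": config.generations,
            "k1": config.k1, "k2": config.k2,
            "k3": config.k3, "k4": config.k4,
            "elitism_count": config.elitism_count,
            "cv_folds": config.cv_folds,
            "seed": config.seed,
        },
        "search_space": {g.name: list(g.values) for g in space.genes},
    }
    return model, report
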