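"""Genetic-algorithm hyperparameter search.

Evolves hyperparameter genomes over the discrete search space, optimizing
validation AUPRC. Two variants: the *plain* GA rebuilds the whole
population from tournament-selected parents each generation; the
*elitist* GA copies the fittest ``elite_count`` individuals unchanged
into the next generation and fills the remaining slots with offspring.
Crossover swaps values gene by gene with a fixed probability; mutation
redraws genes uniformly from their grids. Fitness of a genome is
evaluated once and cached — training a model is the bottleneck, and the
deterministic replay of a run only needs the stored seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CrossoverError, SelectionError
from .genome import GENE_NAMES, Genome, SearchSpace, max_hidden_layers

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Search configuration (defaults follow the benchmark protocol)."""

    population_size: int = 20
    elite_count: int = 4
    tournament_size: int = 2
    crossover_prob: float = 0.3
    mutation_prob: float = 0.2
    n_generations: int = 20
    variant: str = "elitist"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.elite_count < self.population_size:
            raise ValueError("need 0 < elite_count < population_size")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.variant not in ("plain", "elitist"):
            raise ValueError("variant must be 'plain' or 'elitist'")


@dataclass
class Individual:
    genome: Genome
    fitness: float | None = None
    error: str | None = None


@dataclass
class GAHistory:
    """Append-only per-generation log, replayable from the stored seed."""

    config: GAConfig
    rows: list[dict] = field(default_factory=list)

    def log(self, generation: int, index: int, ind: Individual,
            parents: tuple[int, int] | None = None):
        self.rows.append({
            "generation": generation, "index": index,
            "genome": ind.genome.to_json(), "fitness": ind.fitness,
            "parent_a": None if parents is None else parents[0],
            "parent_b": None if parents is None else parents[1],
            "error": ind.error,
        })

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def best_trajectory(self) -> list[float]:
        """Best fitness observed up to and including each generation."""
        best, out = -np.inf, []
        df = self.to_dataframe()
        for g in sorted(df["generation"].unique()):
            best = max(best, df[df["generation"] == g]["fitness"].max())
            out.append(float(best))
        return out


# ----------------------------------------------------------------------

def search_space_size(space: SearchSpace | None = None,
                      include_hidden_layers: bool = False) -> int:
    """Number of genomes in the search space.

    Excluding the hidden-layer gene the size is the plain product of the
    grid cardinalities. Including it, the admissible hidden-layer counts
    depend on the hidden size, so the hidden-size grid contributes
    ``sum(len(valid counts for h))`` instead of its cardinality.
    """
    space = space or SearchSpace()
    others = [g for g in GENE_NAMES if g not in ("hidden_size", "n_hidden_layers")]
    base = int(np.prod([len(space.grids[g]) for g in others], dtype=object))
    if not include_hidden_layers:
        return base * len(space.grids["hidden_size"])
    return base * sum(len(space.valid_hidden_layer_counts(h))
                      for h in space.grids["hidden_size"])


def enumerate_genomes(space: SearchSpace, cell_type: str = "LSTM"):
    """Exhaustively yield every valid genome (brute-force oracle)."""
    names = list(GENE_NAMES)
    for values in itertools.product(*(space.grids[n] for n in names)):
        g = Genome(cell_type=cell_type, **dict(zip(names, values)))
        if g.n_hidden_layers <= max_hidden_layers(g.hidden_size):
            yield g


def random_genome(space: SearchSpace, cell_type: str,
                  rng: np.random.Generator) -> Genome:
    """Draw each gene uniformly from its grid (hidden-layer cap respected)."""
    values = {}
    for name in GENE_NAMES:
        if name == "n_hidden_layers":
            choices = space.valid_hidden_layer_counts(values["hidden_size"])
        else:
            choices = space.grids[name]
        values[name] = choices[int(rng.integers(len(choices)))]
    return Genome(cell_type=cell_type, **values)


def init_population(space: SearchSpace, config: GAConfig, cell_type: str,
                    rng: np.random.Generator | None = None) -> list[Individual]:
    rng = rng or np.random.default_rng(config.seed)
    return [Individual(random_genome(space, cell_type, rng))
            for _ in range(config.population_size)]


def _tournament_index(population: Sequence[Individual], config: GAConfig,
                      rng: np.random.Generator) -> int:
    if config.tournament_size > len(population):
        raise SelectionError(
            f"tournament size {config.tournament_size} exceeds population "
            f"{len(population)}")
    idx = rng.choice(len(population), size=config.tournament_size, replace=False)
    return min(sorted(idx), key=lambda i: (-population[i].fitness, i))


def tournament_select(population: Sequence[Individual], config: GAConfig,
                      rng: np.random.Generator) -> Individual:
    """Fittest of ``tournament_size`` uniform draws without replacement.

    Ties break toward the earlier population index.
    """
    return population[_tournament_index(population, config, rng)]


def _clamp_hidden_layers(genome: Genome) -> Genome:
    cap = max_hidden_layers(genome.hidden_size)
    if genome.n_hidden_layers > cap:
        logger.debug("clamping n_hidden_layers %d -> %d (hidden_size %d)",
                     genome.n_hidden_layers, cap, genome.hidden_size)
        return genome.replace(n_hidden_layers=cap)
    return genome


def crossover(parent_a: Genome, parent_b: Genome, config: GAConfig,
              rng: np.random.Generator) -> tuple[Genome, Genome]:
    """Swap each gene between the parents with ``crossover_prob``."""
    if parent_a.cell_type != parent_b.cell_type:
        raise CrossoverError(
            f"cannot cross {parent_a.cell_type} with {parent_b.cell_type}")
    a, b = dict(parent_a.genes()), dict(parent_b.genes())
    for name in GENE_NAMES:
        if rng.random() < config.crossover_prob:
            a[name], b[name] = b[name], a[name]
    ca = _clamp_hidden_layers(Genome(cell_type=parent_a.cell_type, **a))
    cb = _clamp_hidden_layers(Genome(cell_type=parent_b.cell_type, **b))
    return ca, cb


def mutate(genome: Genome, space: SearchSpace, config: GAConfig,
           rng: np.random.Generator) -> Genome:
    """Redraw each gene with ``mutation_prob`` from its full grid.

    The redraw may return the current value. The hidden-layer gene is
    drawn from the counts admissible for the (possibly mutated) hidden
    size; mutating the hidden size re-clamps the hidden-layer count.
    """
    values = dict(genome.genes())
    for name in GENE_NAMES:
        if rng.random() < config.mutation_prob:
            if name == "n_hidden_layers":
                choices = space.valid_hidden_layer_counts(values["hidden_size"])
            else:
                choices = space.grids[name]
            values[name] = choices[int(rng.integers(len(choices)))]
    return _clamp_hidden_layers(Genome(cell_type=genome.cell_type, **values))


def evolve(space: SearchSpace, config: GAConfig,
           fitness_callback: Callable[[Genome], float],
           cell_type: str = "LSTM") -> tuple[Individual, GAHistory]:
    """Run the GA; returns the best individual ever evaluated + history.

    ``fitness_callback`` maps a genome to a score in [0, 1] (typically:
    train the genome's model, return validation AUPRC). A callback
    failure records fitness 0 with the error note and the run continues.
    Identical genomes share one cached evaluation.
    """
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, tuple[float, str | None]] = {}
    history = GAHistory(config=config)

    def assess(ind: Individual) -> Individual:
        key = ind.genome.key()
        if key not in cache:
            try:
                cache[key] = (float(fitness_callback(ind.genome)), None)
            except Exception as exc:  # noqa: BLE001 - run must continue
                logger.warning("fitness evaluation failed: %s", exc)
                cache[key] = (0.0, repr(exc))
        ind.fitness, ind.error = cache[key]
        return ind

    population = [assess(i) for i in init_population(space, config, cell_type, rng)]
    for i, ind in enumerate(population):
        history.log(0, i, ind)
    best = max(population, key=lambda i: i.fitness)

    for gen in range(1, config.n_generations + 1):
        n_offspring = config.population_size - (
            config.elite_count if config.variant == "elitist" else 0)
        offspring: list[Individual] = []
        parentage: list[tuple[int, int]] = []
        while len(offspring) < n_offspring:
            ia = _tournament_index(population, config, rng)
            ib = _tournament_index(population, config, rng)
            pa, pb = population[ia], population[ib]
            for child in crossover(pa.genome, pb.genome, config, rng):
                if len(offspring) < n_offspring:
                    offspring.append(Individual(mutate(child, space, config, rng)))
                    parentage.append((ia, ib))
        if config.variant == "elitist":
            order = sorted(range(len(population)),
                           key=lambda i: (-population[i].fitness, i))
            elites = [Individual(population[i].genome, population[i].fitness,
                                 population[i].error)
                      for i in order[:config.elite_count]]
        else:
            elites = []
        population = elites + [assess(c) for c in offspring]
        for i, ind in enumerate(population):
            parents = None if i < len(elites) else parentage[i - len(elites)]
            history.log(gen, i, ind, parents)
        gen_best = max(population, key=lambda i: i.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
    return best, history


class GeneticHyperparameterSearch:
    """Estimator-style wrapper: evolve a genome, refit the best model.

    ``fit(X, y)`` carves a validation split off the training data (or
    uses an explicit one), runs :func:`evolve` with validation AUPRC as
    the fitness, then refits the winning genome on all supplied data.
    """

    def __init__(self, cell_type: str = "LSTM", config: GAConfig = GAConfig(),
                 space: SearchSpace | None = None, val_fraction: float = 0.25,
                 random_state: int = 0):
        self.cell_type = cell_type
        self.config = config
        self.space = space or SearchSpace()
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None) -> "GeneticHyperparameterSearch":
        from .model import RecurrentOffTargetClassifier
        from .training import stratified_split_indices

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X_val is None:
            f = self.val_fraction
            tr, va, _ = stratified_split_indices(
                y, (1.0 - f, f, 0.0 + 1e-12), seed=self.random_state)
            X_tr, y_tr, X_val, y_val = X[tr], y[tr], X[va], y[va]
        else:
            X_tr, y_tr = X, y

        def fitness(genome: Genome) -> float:
            est = RecurrentOffTargetClassifier.from_genome(
                genome, random_state=self.random_state)
            est.fit(X_tr, y_tr)
            return est.score(X_val, y_val)

        best, history = evolve(self.space, self.config, fitness, self.cell_type)
        self.best_genome_ = best.genome
        self.best_score_ = best.fitness
        self.history_ = history
        from .model import RecurrentOffTargetClassifier as _C
        self.best_estimator_ = _C.from_genome(
            self.best_genome_, random_state=self.random_state).fit(X, y)
        return self

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)

    def predict(self, X):
        return self.best_estimator_.predict(X)
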