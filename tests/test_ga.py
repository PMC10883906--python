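"""Genetic-algorithm operators and search behavior."""

import numpy as np
import pytest

from guideoff.exceptions import CrossoverError, SelectionError
from guideoff.ga import (GAConfig, Individual, crossover, enumerate_genomes,
                         evolve, init_population, mutate, random_genome,
                         search_space_size, tournament_select)
from guideoff.genome import GENE_NAMES, Genome, SearchSpace, max_hidden_layers


def _small_space(**extra):
    """Search space with three free genes (4 x 4 x 4 = 64 genomes)."""
    grids = {
        "batch_size": (32,), "epochs": (10,), "n_recurrent_layers": (1,),
        "bidirectional": (False,), "n_hidden_layers": (0,),
        "dropout_p": (0.1, 0.2, 0.3, 0.4),
        "hidden_size": (32, 64, 128, 256),
        "learning_rate": (1e-4, 1e-3, 1e-2, 1e-1),
    }
    grids.update(extra)
    return SearchSpace(grids=grids)


def test_search_space_size_is_72000():
    assert search_space_size(SearchSpace(), include_hidden_layers=False) == 72000


def test_search_space_size_with_hidden_layers_matches_enumeration():
    space = SearchSpace()
    expected = sum(1 for _ in enumerate_genomes(space))
    assert search_space_size(space, include_hidden_layers=True) == expected
    # closed form: hidden-size grid contributes admissible counts per size
    per_size = [len(space.valid_hidden_layer_counts(h))
                for h in space.grids["hidden_size"]]
    assert search_space_size(space, include_hidden_layers=True) == \
        sum(per_size) * (72000 // len(per_size))


def test_singleton_space_has_one_genome():
    space = _small_space(dropout_p=(0.1,), hidden_size=(32,),
                        learning_rate=(1e-3,))
    assert search_space_size(space, include_hidden_layers=True) == 1
    cfg = GAConfig(population_size=4, elite_count=1, seed=0)
    pop = init_population(space, cfg, "LSTM")
    assert all(ind.genome == pop[0].genome for ind in pop)


def test_init_population_uniform_over_grid():
    space = _small_space()
    rng = np.random.default_rng(0)
    draws = [random_genome(space, "RNN", rng).dropout_p for _ in range(10000)]
    for v in space.grids["dropout_p"]:
        freq = np.mean(np.array(draws) == v)
        assert abs(freq - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 10000)


def test_init_population_deterministic_under_seed():
    space = _small_space()
    cfg = GAConfig(seed=42)
    a = init_population(space, cfg, "GRU")
    b = init_population(space, cfg, "GRU")
    assert [i.genome for i in a] == [j.genome for j in b]


def test_tournament_selects_best_of_pair():
    cfg = GAConfig(tournament_size=2)
    rng = np.random.default_rng(0)
    space = _small_space()
    g = random_genome(space, "LSTM", rng)
    pop = [Individual(g, 0.9), Individual(g, 0.1)]
    for _ in range(20):
        assert tournament_select(pop, cfg, rng).fitness == 0.9
    full = GAConfig(tournament_size=4, population_size=5, elite_count=1)
    pop4 = [Individual(g, f) for f in (0.3, 0.8, 0.1, 0.5)]
    assert tournament_select(pop4, full, rng).fitness == 0.8


def test_tournament_rank_probabilities_closed_form():
    # size-2 without replacement: P(rank r) = 2(n-r)/(n(n-1))
    n, trials = 10, 20000
    space = _small_space()
    rng = np.random.default_rng(1)
    g = random_genome(space, "LSTM", rng)
    pop = [Individual(g, (n - r) / n) for r in range(n)]  # index 0 is best
    cfg = GAConfig(tournament_size=2)
    counts = np.zeros(n)
    for _ in range(trials):
        winner = tournament_select(pop, cfg, rng)
        counts[int(round((1 - winner.fitness) * n))] += 1
    for r0 in range(n):
        p = 2 * (n - (r0 + 1)) / (n * (n - 1))
        assert abs(counts[r0] / trials - p) < 3 * np.sqrt(p * (1 - p) / trials) + 1e-9


def test_tournament_size_exceeding_population_raises():
    space = _small_space()
    rng = np.random.default_rng(0)
    pop = [Individual(random_genome(space, "LSTM", rng), 0.5)]
    with pytest.raises(SelectionError):
        tournament_select(pop, GAConfig(tournament_size=2), rng)


def test_crossover_probability_extremes_and_identity():
    space = _small_space()
    rng = np.random.default_rng(2)
    a, b = (random_genome(space, "LSTM", rng) for _ in range(2))
    ca, cb = crossover(a, b, GAConfig(crossover_prob=0.0), rng)
    assert (ca, cb) == (a, b)
    ca, cb = crossover(a, b, GAConfig(crossover_prob=1.0), rng)
    assert (ca, cb) == (b, a)
    ca, cb = crossover(a, a, GAConfig(crossover_prob=0.5), rng)
    assert ca == a and cb == a


def test_crossover_rejects_mixed_cell_types():
    space = _small_space()
    rng = np.random.default_rng(3)
    with pytest.raises(CrossoverError):
        crossover(random_genome(space, "LSTM", rng),
                  random_genome(space, "GRU", rng), GAConfig(), rng)


def test_crossover_swap_rate_matches_probability():
    space = _small_space()
    rng = np.random.default_rng(4)
    trials, p = 10000, 0.3
    cfg = GAConfig(crossover_prob=p)
    a = Genome("LSTM", 32, 10, 1, False, 0.1, 32, 0, 1e-4)
    b = Genome("LSTM", 32, 10, 1, False, 0.4, 256, 0, 1e-1)
    swapped = np.zeros(3)
    free = ("dropout_p", "hidden_size", "learning_rate")
    for _ in range(trials):
        ca, _ = crossover(a, b, cfg, rng)
        for j, gene in enumerate(free):
            swapped[j] += getattr(ca, gene) == getattr(b, gene)
    for j in range(3):
        assert abs(swapped[j] / trials - p) < 3 * np.sqrt(p * (1 - p) / trials)


def test_mutation_extremes_and_redraw_rate():
    space = _small_space()
    rng = np.random.default_rng(5)
    g = random_genome(space, "RNN", rng)
    assert mutate(g, space, GAConfig(mutation_prob=0.0), rng) == g
    singleton = _small_space(dropout_p=(0.1,), hidden_size=(32,),
                             learning_rate=(1e-3,))
    gs = random_genome(singleton, "RNN", rng)
    assert mutate(gs, singleton, GAConfig(mutation_prob=1.0), rng) == gs
    # p=1 on a 4-value grid: change rate = 1 - 1/4
    trials, changed = 10000, 0
    cfg = GAConfig(mutation_prob=1.0)
    for _ in range(trials):
        changed += mutate(g, space, cfg, rng).dropout_p != g.dropout_p
    p = 0.75
    assert abs(changed / trials - p) < 3 * np.sqrt(p * (1 - p) / trials)


def test_mutation_and_crossover_preserve_validity():
    space = SearchSpace()  # full space: hidden-layer cap is live
    rng = np.random.default_rng(6)
    cfg = GAConfig(crossover_prob=0.5, mutation_prob=0.5)
    for _ in range(300):
        a = random_genome(space, "LSTM", rng)
        b = random_genome(space, "LSTM", rng)
        ca, cb = crossover(a, b, cfg, rng)
        for g in (ca, cb, mutate(ca, space, cfg, rng)):
            g.validate(space)
            assert g.n_hidden_layers <= max_hidden_layers(g.hidden_size)


def _fitness_landscape(space):
    genomes = list(enumerate_genomes(space))
    rng = np.random.default_rng(99)
    values = rng.permutation(len(genomes)) / len(genomes)
    table = {g.key(): float(v) for g, v in zip(genomes, values)}
    best = max(table, key=table.get)
    return (lambda g: table[g.key()]), best


def smooth_landscape(space, free_genes=("dropout_p", "hidden_size",
                                        "learning_rate")):
    """Separable unimodal fitness with a unique optimum mid-grid."""
    targets = {g: len(space.grids[g]) // 2 for g in free_genes}

    def fitness(genome):
        s = 0.0
        for name in free_genes:
            grid = space.grids[name]
            i = grid.index(getattr(genome, name))
            s += 1.0 - abs(i - targets[name]) / len(grid)
        return s / len(free_genes)

    best_key = max(enumerate_genomes(space), key=fitness).key()
    return fitness, best_key


def test_elitist_ga_finds_exhaustive_optimum():
    space = _small_space()
    fitness, best_key = smooth_landscape(space)
    cfg = GAConfig(seed=17)  # benchmark config: 20/4/2, 0.3/0.2, 20 gens
    best, history = evolve(space, cfg, fitness)
    assert best.genome.key() == best_key
    traj = history.best_trajectory()
    assert traj == sorted(traj)  # monotone best-so-far


def test_plain_ga_runs_and_population_size_constant():
    space = _small_space()
    fitness, _ = _fitness_landscape(space)
    cfg = GAConfig(variant="plain", n_generations=5, seed=3)
    best, history = evolve(space, cfg, fitness)
    df = history.to_dataframe()
    assert (df.groupby("generation").size() == cfg.population_size).all()
    assert 0 <= best.fitness <= 1


def test_zero_generations_returns_best_of_initial_population():
    space = _small_space()
    fitness, _ = _fitness_landscape(space)
    cfg = GAConfig(n_generations=0, seed=8)
    best, history = evolve(space, cfg, fitness)
    df = history.to_dataframe()
    assert set(df["generation"]) == {0}
    assert best.fitness == df["fitness"].max()


def test_evolve_replay_reproduces_history():
    space = _small_space()
    fitness, _ = _fitness_landscape(space)
    cfg = GAConfig(n_generations=4, seed=21)
    _, h1 = evolve(space, cfg, fitness)
    _, h2 = evolve(space, cfg, fitness)
    assert h1.rows == h2.rows


def test_callback_failure_recorded_as_zero_fitness():
    space = _small_space()

    def flaky(genome):
        if genome.dropout_p == 0.1:
            raise RuntimeError("boom")
        return 0.5

    cfg = GAConfig(n_generations=1, seed=2)
    best, history = evolve(space, cfg, flaky)
    df = history.to_dataframe()
    failed = df[df["error"].notna()]
    assert len(failed) > 0 and (failed["fitness"] == 0.0).all()
    assert best.fitness == 0.5
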