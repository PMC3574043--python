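"""GA/SVM wrapper feature selection.

A genetic algorithm evolves boolean inclusion masks ("chromosomes") over
the candidate gene pool. Each chromosome is scored by

    fitness = (1 - weight) * accuracy
            + weight * (numberOfAllGenes - numberOfSelectedGenes) / numberOfAllGenes

where *accuracy* is the internally cross-validated accuracy of a
Gaussian-kernel SVM trained on the selected genes only, and the second
term rewards parsimony. With the default weight of 0.2 the selector
favours small gene sets that classify well in combination.

One generation: 160 offspring are bred from roulette-selected parents by
uniform crossover, 20 roulette-selected chromosomes are copied and
mutated (bit flips at rate 0.0015), and the best 200 of the pooled
200 + 160 + 20 = 380 chromosomes survive. After 25 generations the
highest-fitness chromosome's gene set is returned. Because parents stay
in the pool, the best fitness is non-decreasing across generations.

Running the GA many times and counting how often each gene appears in
the final sets gives a frequency ranking comparable to per-gene scores
from other selectors; redundant genes split their counts because a
single run tends to include only one member of a redundant group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from biomarker_ga import _svm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Settings of one GA/SVM run.

    ``init_inclusion_prob`` defaults to ``mean_initial_genes / n_genes``
    so that initial chromosomes contain about 15 genes; with
    ``exact_initial_size`` every initial chromosome has exactly that
    many genes instead of a binomial number.
    """

    population_size: int = 200
    generations: int = 25
    n_offspring: int = 160
    n_mutants: int = 20
    bit_flip_rate: float = 0.0015
    mean_initial_genes: float = 15.0
    init_inclusion_prob: float | None = None
    exact_initial_size: bool = False
    weight: float = 0.2
    internal_cv_folds: int = 6
    svm_c: float = 1.0

    def validate(self) -> None:
        if self.population_size < 1 or self.generations < 0:
            raise ValueError("population_size must be >= 1, generations >= 0")
        if self.n_offspring < 0 or self.n_mutants < 0:
            raise ValueError("offspring/mutant counts must be non-negative")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")
        if not 0.0 <= self.bit_flip_rate <= 1.0:
            raise ValueError("bit_flip_rate must be in [0, 1]")
        if self.internal_cv_folds < 2:
            raise ValueError("internal_cv_folds must be >= 2")

    def inclusion_prob(self, n_genes: int) -> float:
        p = self.init_inclusion_prob
        if p is None:
            p = self.mean_initial_genes / n_genes
        return min(max(p, 0.0), 1.0)


@dataclass(frozen=True)
class FitnessValue:
    """Fitness of one chromosome and its two components."""

    fitness: float
    accuracy: float
    parsimony: float


@dataclass(frozen=True)
class GARunResult:
    """Outcome of a single GA run."""

    best_genes: tuple[str, ...]
    best_fitness: FitnessValue
    trace_best: tuple[float, ...]
    trace_mean: tuple[float, ...]
    config: GAConfig
    seed: int | None = None


def prepare_inputs(
    expression: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Expression (genes x samples) + annotation -> (X, y, gene names).

    X is samples x genes, C-contiguous float64; y is a 0/1 coding of the
    two class labels (lexicographically first label = 1).
    """
    ann = annotation.set_index("sample_id").loc[list(expression.columns)]
    labels = ann["class_label"].to_numpy()
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {classes}")
    y = (labels == classes[0]).astype(np.float64)
    x = np.ascontiguousarray(expression.to_numpy().T, dtype=np.float64)
    return x, y, list(expression.index)


def fitness(
    mask: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    config: GAConfig,
    n_all_genes: int | None = None,
) -> FitnessValue:
    """Score one chromosome.

    An empty chromosome is assigned fitness 0 (logged) so evolution can
    proceed past degenerate masks.
    """
    n_all = n_all_genes if n_all_genes is not None else mask.size
    n_sel = int(mask.sum())
    parsimony = (n_all - n_sel) / n_all
    if n_sel == 0:
        logger.debug("empty chromosome scored with fitness 0")
        return FitnessValue(0.0, 0.0, parsimony)
    x_sel = np.ascontiguousarray(x[:, mask])
    acc = _svm.cv_accuracy(x_sel, y, folds, c=config.svm_c, gamma=1.0 / n_sel)
    fit = (1.0 - config.weight) * acc + config.weight * parsimony
    return FitnessValue(fit, acc, parsimony)


def init_population(
    config: GAConfig, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """population_size x n_genes boolean masks; empty rows are redrawn."""
    p = config.inclusion_prob(n_genes)
    if config.exact_initial_size:
        k = max(1, int(round(config.mean_initial_genes)))
        pop = np.zeros((config.population_size, n_genes), dtype=bool)
        for i in range(config.population_size):
            pop[i, rng.choice(n_genes, size=k, replace=False)] = True
        return pop
    pop = rng.random((config.population_size, n_genes)) < p
    for i in np.flatnonzero(~pop.any(axis=1)):
        while not pop[i].any():
            pop[i] = rng.random(n_genes) < p
    return pop


def roulette_select(
    fitnesses: np.ndarray, rng: np.random.Generator
) -> int:
    """Index drawn with probability proportional to fitness.

    All-zero fitness degrades to uniform selection (logged).
    """
    total = fitnesses.sum()
    if total <= 0:
        logger.debug("all-zero fitness: roulette selection degrades to uniform")
        return int(rng.integers(len(fitnesses)))
    return int(rng.choice(len(fitnesses), p=fitnesses / total))


def uniform_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Each position copied from either parent with probability 0.5."""
    if parent_a.shape != parent_b.shape:
        raise ValueError("parent masks must have equal length")
    take_a = rng.random(parent_a.size) < 0.5
    return np.where(take_a, parent_a, parent_b)


def mutate(
    mask: np.ndarray, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Flip each bit independently with probability ``bit_flip_rate``."""
    flips = rng.random(mask.size) < config.bit_flip_rate
    return mask ^ flips


def run_ga(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    config: GAConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> GARunResult:
    """One GA/SVM run on the candidate pool; returns the best gene set.

    The internal cross-validation split is stratified by class, drawn
    once from the run's RNG and frozen, so that cached fitness values
    stay valid within the run.
    """
    config = config or GAConfig()
    config.validate()
    x, y, genes = prepare_inputs(expression, annotation)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_echo = None if isinstance(seed, np.random.Generator) else int(seed)
    n_genes = len(genes)

    folds = _svm.stratified_folds(y, config.internal_cv_folds, rng)
    cache: dict[bytes, FitnessValue] = {}

    def evaluate(mask: np.ndarray) -> FitnessValue:
        key = mask.tobytes()
        hit = cache.get(key)
        if hit is None:
            hit = fitness(mask, x, y, folds, config)
            cache[key] = hit
        return hit

    population = list(init_population(config, n_genes, rng))
    fits = [evaluate(m) for m in population]
    trace_best: list[float] = []
    trace_mean: list[float] = []

    for _ in range(config.generations):
        fvals = np.array([f.fitness for f in fits])
        children: list[np.ndarray] = []
        for _ in range(config.n_offspring):
            ia = roulette_select(fvals, rng)
            ib = roulette_select(fvals, rng)
            children.append(uniform_crossover(population[ia], population[ib], rng))
        for _ in range(config.n_mutants):
            im = roulette_select(fvals, rng)
            children.append(mutate(population[im], config, rng))
        pool = population + children
        pool_fits = fits + [evaluate(m) for m in children]
        order = np.argsort(-np.array([f.fitness for f in pool_fits]), kind="stable")
        keep = order[: config.population_size]
        population = [pool[i] for i in keep]
        fits = [pool_fits[i] for i in keep]
        trace_best.append(fits[0].fitness)
        trace_mean.append(float(np.mean([f.fitness for f in fits])))

    best_idx = int(np.argmax([f.fitness for f in fits]))
    best_mask = population[best_idx]
    best = fits[best_idx]
    best_genes = tuple(g for g, m in zip(genes, best_mask) if m)
    return GARunResult(
        best_genes=best_genes,
        best_fitness=best,
        trace_best=tuple(trace_best),
        trace_mean=tuple(trace_mean),
        config=config,
        seed=seed_echo,
    )


def run_many(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    config: GAConfig | None = None,
    n_runs: int = 500,
    base_seed: int = 0,
) -> tuple[list[tuple[str, ...]], pd.DataFrame]:
    """Independent seeded GA runs plus the gene frequency ranking.

    Each run draws its RNG stream from ``SeedSequence(base_seed)``, so
    the full list of final gene sets is reproducible and no run shares
    randomness with another.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    from biomarker_ga.rankers import frequency_rank

    children = np.random.SeedSequence(base_seed).spawn(n_runs)
    sets: list[tuple[str, ...]] = []
    for i, child in enumerate(children):
        result = run_ga(expression, annotation, config, seed=np.random.default_rng(child))
        sets.append(result.best_genes)
        if (i + 1) % 50 == 0:
            logger.info("GA run %d/%d complete", i + 1, n_runs)
    ranking = frequency_rank(sets)
    return sets, ranking.table


def write_gene_sets(sets: list[tuple[str, ...]], path: str | Path) -> None:
    """One final gene set per line, tab-separated symbols."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join(s) + "\n")


def read_gene_sets(path: str | Path) -> list[tuple[str, ...]]:
    sets = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            sets.append(tuple(line.split("\t")))
    return sets
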