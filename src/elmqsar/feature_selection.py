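"""GA descriptor-subset search with usage-frequency importance.

Descriptor selection runs in two stages.  A Welch two-sample t-test first
discards descriptors whose class means are statistically indistinguishable
(p >= alpha, default 0.001); per-descriptor tests do not depend on the
subset, so they are applied once rather than folded into the subset
fitness.  A binary-chromosome genetic algorithm then searches subsets of
the survivors, scoring each chromosome by the Akaike information criterion
of the ordinary least-squares fit of the class codes on the included
descriptors (fitness = -AIC, maximised):

    AIC = n * ln(RSS / n) + 2 * (k + 1)

with k included descriptors and an intercept.  Descriptor importance is the
*usage frequency*: the number of chromosomes in the final population whose
subset includes the descriptor, ranging from 0 (never used) to the
population size (used by every chromosome).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import ACTIVE, INACTIVE, LabeledDataset
from .errors import ConfigError, DegenerateProblemError

logger = logging.getLogger(__name__)

AIC_RSS_FLOOR = 1e-12  # guards ln(0) on perfect fits
RIDGE_FALLBACK = 1e-8  # regularizer for singular (collinear) designs


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for the subset-selection GA.

    The GA hyperparameters (mutation probability 0.03, population size 100,
    generation cap 1000) are shared with the weight-refinement GA.
    ``usage_cutoff`` is the usage frequency a descriptor must reach to
    enter the selected subset; 90 marks the strongly-preferred descriptors
    under a population of 100 but is dataset-dependent.
    """

    population_size: int = 100
    mutation_prob: float = 0.03
    max_generations: int = 1000
    crossover_prob: float = 0.8
    elitism_count: int = 2
    ttest_alpha: float = 0.001
    usage_cutoff: int = 90
    stall_generations: int = 200
    cumulative_usage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.max_generations < 0:
            raise ConfigError("population_size and max_generations must be positive")
        if not 0.0 < self.mutation_prob < 1.0:
            raise ConfigError("mutation_prob must be in (0, 1)")
        if not 0.0 < self.crossover_prob < 1.0:
            raise ConfigError("crossover_prob must be in (0, 1)")
        if not 0 <= self.elitism_count < self.population_size:
            raise ConfigError("elitism_count must be < population_size")
        if not 0.0 < self.ttest_alpha <= 1.0:
            raise ConfigError("ttest_alpha must be in (0, 1]")
        if not 0 <= self.usage_cutoff <= self.population_size:
            raise ConfigError("usage_cutoff must be in [0, population_size]")


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``usage`` maps every input descriptor to its usage frequency in the
    final GA population (0 for descriptors removed by the prefilter);
    ``selected`` holds the descriptors whose usage reached the cutoff,
    sorted by usage descending then name.
    """

    usage: dict[str, int]
    selected: list[str]
    prefilter_pvalues: dict[str, float]
    best_fitness_trace: list[float]
    seed: int
    population_size: int = 100
    generations_run: int = 0

    def ranking(self) -> list[tuple[str, int]]:
        """All descriptors sorted by usage descending, name ascending."""
        return sorted(self.usage.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dict(self) -> dict:
        return {
            "usage": self.usage,
            "selected": self.selected,
            "prefilter_pvalues": self.prefilter_pvalues,
            "best_fitness_trace": self.best_fitness_trace,
            "seed": self.seed,
            "population_size": self.population_size,
            "generations_run": self.generations_run,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            usage={k: int(v) for k, v in d["usage"].items()},
            selected=list(d["selected"]),
            prefilter_pvalues={
                k: float(v) for k, v in d["prefilter_pvalues"].items()
            },
            best_fitness_trace=[float(v) for v in d["best_fitness_trace"]],
            seed=int(d["seed"]),
            population_size=int(d.get("population_size", 100)),
            generations_run=int(d.get("generations_run", 0)),
        )


def ttest_prefilter(
    dataset: LabeledDataset, alpha: float = 0.001
) -> tuple[list[str], dict[str, float]]:
    """Welch two-sample t-test screen on every descriptor.

    Returns the descriptors with two-sided p < ``alpha`` (in input order)
    and the p-value of every descriptor.  Unequal variances are assumed.
    """
    active = dataset.matrix.values[dataset.labels == ACTIVE]
    inactive = dataset.matrix.values[dataset.labels == INACTIVE]
    if active.shape[0] < 2 or inactive.shape[0] < 2:
        raise DegenerateProblemError(
            "the t-test prefilter needs >= 2 compounds per class"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(active, inactive, axis=0, equal_var=False)
        pvalues = np.asarray(result.pvalue, dtype=float)
    # a descriptor constant in both classes yields NaN: no separation
    pvalues = np.where(np.isfinite(pvalues), pvalues, 1.0)
    names = dataset.matrix.descriptor_names
    pmap = {d: float(p) for d, p in zip(names, pvalues)}
    kept = [d for d, p in zip(names, pvalues) if p < alpha]
    if not kept:
        logger.warning("no descriptor passed the t-test prefilter (alpha=%g)", alpha)
    return kept, pmap


def aic_linear(X: np.ndarray, y: np.ndarray) -> float:
    """AIC of the OLS fit (with intercept) of y on the columns of X.

    ``AIC = n * ln(RSS / n) + 2 * (k + 1)`` where k is the number of
    columns.  RSS is floored at 1e-12 so perfect fits stay finite; a
    singular design falls back to a tiny ridge penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if k == 0:
        raise DegenerateProblemError("AIC of an empty descriptor subset")
    if n <= k + 2:
        raise DegenerateProblemError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), X])
    coef, residual, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.debug("singular design (k=%d); ridge fallback", k)
        gram = design.T @ design + RIDGE_FALLBACK * np.eye(design.shape[1])
        coef = np.linalg.solve(gram, design.T @ y)
    rss = float(np.sum((y - design @ coef) ** 2))
    rss = max(rss, AIC_RSS_FLOOR)
    return n * math.log(rss / n) + 2.0 * (k + 1)


def _repair_empty(population: np.ndarray, rng: np.random.Generator) -> None:
    """Set one random bit in any all-zero chromosome (in place)."""
    empty = ~population.any(axis=1)
    for i in np.flatnonzero(empty):
        population[i, rng.integers(population.shape[1])] = True


def _rank_selection_probs(fitness: np.ndarray) -> np.ndarray:
    """Linear rank-scaled selection probabilities (best rank = highest)."""
    order = np.argsort(np.argsort(fitness, kind="stable"), kind="stable")
    ranks = order + 1.0  # worst gets 1, best gets pop
    return ranks / ranks.sum()


def select_descriptors_ga(
    dataset: LabeledDataset, config: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Search descriptor subsets with a binary-chromosome GA.

    The dataset is assumed standardized.  Each chromosome is one bit per
    descriptor surviving the t-test prefilter; fitness is -AIC of the OLS
    fit of the class codes on the included descriptors.  Elites are copied
    unchanged; parents are drawn by rank-scaled fitness-proportional
    selection, recombined by uniform crossover, and mutated per bit.
    The run is deterministic given ``config.seed``.
    """
    kept, pvalues = ttest_prefilter(dataset, config.ttest_alpha)
    all_names = dataset.matrix.descriptor_names
    usage = {d: 0 for d in all_names}
    if len(kept) < 2:
        raise DegenerateProblemError(
            f"only {len(kept)} descriptor(s) survive the prefilter; need >= 2"
        )
    sub = dataset.matrix.subset(kept)
    X = sub.values
    y = dataset.y
    m = len(kept)
    pop_size = config.population_size
    rng = np.random.default_rng(config.seed)

    population = rng.random((pop_size, m)) < 0.5
    _repair_empty(population, rng)

    cache: dict[bytes, float] = {}

    def fitness_of(chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        hit = cache.get(key)
        if hit is None:
            cols = np.flatnonzero(chrom)
            hit = -aic_linear(X[:, cols], y)
            cache[key] = hit
        return hit

    fitness = np.array([fitness_of(c) for c in population])
    cumulative = population.sum(axis=0).astype(np.int64)
    trace: list[float] = [float(fitness.max())]
    best_fit = trace[0]
    stall = 0
    generations = 0

    for _ in range(config.max_generations):
        generations += 1
        probs = _rank_selection_probs(fitness)
        elite_idx = np.argsort(-fitness, kind="stable")[: config.elitism_count]
        children = np.empty_like(population)
        children[: config.elitism_count] = population[elite_idx]
        n_rest = pop_size - config.elitism_count
        parents = rng.choice(pop_size, size=(n_rest, 2), p=probs)
        pa = population[parents[:, 0]]
        pb = population[parents[:, 1]]
        do_cx = rng.random(n_rest) < config.crossover_prob
        mask = rng.random((n_rest, m)) < 0.5
        offspring = np.where(mask, pa, pb)
        offspring[~do_cx] = pa[~do_cx]
        mut = rng.random((n_rest, m)) < config.mutation_prob
        offspring ^= mut
        children[config.elitism_count:] = offspring
        _repair_empty(children, rng)
        population = children
        fitness = np.array([fitness_of(c) for c in population])
        cumulative += population.sum(axis=0)
        gen_best = float(fitness.max())
        if gen_best > best_fit + 1e-12:
            best_fit = gen_best
            stall = 0
        else:
            stall += 1
        trace.append(max(best_fit, gen_best))
        if stall >= config.stall_generations:
            logger.info("selection GA stopped after %d stagnant generations", stall)
            break

    if config.cumulative_usage:
        # average usage over all generations, rounded to an integer count
        counts = np.rint(cumulative / (generations + 1)).astype(int)
    else:
        counts = population.sum(axis=0)
    for d, c in zip(kept, counts):
        usage[d] = int(c)
    selected = sorted(
        (d for d in all_names if usage[d] >= config.usage_cutoff),
        key=lambda d: (-usage[d], d),
    )
    logger.info(
        "selection: %d/%d descriptors past prefilter, %d selected "
        "(cutoff %d) after %d generations",
        m, len(all_names), len(selected), config.usage_cutoff, generations,
    )
    return SelectionResult(
        usage=usage,
        selected=selected,
        prefilter_pvalues=pvalues,
        best_fitness_trace=trace,
        seed=config.seed,
        population_size=pop_size,
        generations_run=generations,
    )
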