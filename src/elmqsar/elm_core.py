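"""The linear QSAR model: scoring, initialization, GA refinement, prediction.

A compound C with standardized descriptor values x_1..x_M is scored by the
no-intercept weighted sum

    f(C) = sum_i w_i * x_i

against the class codes y in {1 (active), 2 (inactive)}.  Each initial
weight w_i is the univariate least-squares slope of y on descriptor i:

    w_i = sum_j (x_ij - mean(x_i)) (y_j - mean(y)) / sum_j (x_ij - mean(x_i))^2

computed per descriptor independently.  The weight vector is then refined
by a real-coded genetic algorithm maximising a robust fitness of the
residuals r_j = y_j - f(C_j).  The default fitness is the negative total
Andrews' sine loss

    rho(r) = a^2 * (1 - cos(r / a))   for |r| <= pi * a
    rho(r) = 2 * a^2                  otherwise

a bounded, redescending loss that caps the influence of outlying
compounds; a = 1.339 is the conventional 95%-efficiency tuning constant.
A plain sum-of-squares fitness (-RSS) is selectable.

Prediction uses only a scalar threshold on f(C): a compound scores active
when f(C) < threshold (the class codes put actives, code 1, below
inactives, code 2).  The default threshold is the midpoint of the class
means of the training scores; the literal difference of class means is
retained as an alternative mode (see docs/methods.md for why the midpoint
is the default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import (
    ACTIVE,
    INACTIVE,
    DescriptorMatrix,
    LabeledDataset,
    Standardizer,
    standardize,
)
from .errors import ConfigError, DegenerateProblemError

logger = logging.getLogger(__name__)

ANDREWS_A_DEFAULT = 1.339

THRESHOLD_MODES = ("midpoint", "literal_difference")
FITNESS_KINDS = ("andrews_sine", "sum_of_squares")


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the real-coded weight-refinement GA.

    ``search_halfwidth_sds`` bounds each gene to a box of +/- that many
    weight-scales around the initial weight; an unbounded real-coded GA is
    ill-posed.  ``andrews_a`` is the Andrews tuning constant.
    """

    population_size: int = 100
    mutation_prob: float = 0.03
    max_generations: int = 1000
    fitness_kind: str = "andrews_sine"
    andrews_a: float = ANDREWS_A_DEFAULT
    search_halfwidth_sds: float = 5.0
    elitism_count: int = 2
    crossover_prob: float = 0.8
    blx_alpha: float = 0.5
    mutation_sd_frac: float = 0.1
    stall_generations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fitness_kind not in FITNESS_KINDS:
            raise ConfigError(f"fitness_kind must be one of {FITNESS_KINDS}")
        if self.andrews_a <= 0 or self.search_halfwidth_sds <= 0:
            raise ConfigError("andrews_a and search_halfwidth_sds must be > 0")
        if not 0 <= self.elitism_count < self.population_size:
            raise ConfigError("elitism_count must be < population_size")
        if not 0.0 < self.mutation_prob < 1.0:
            raise ConfigError("mutation_prob must be in (0, 1)")


@dataclass
class ELMModel:
    """A fitted linear scorer: descriptor subset, weights, threshold.

    ``standardizer`` holds the training-data z-score statistics applied to
    any matrix before scoring, so predictions are invariant to the raw
    units of new data.
    """

    descriptor_names: list[str]
    weights: np.ndarray
    threshold: float
    threshold_mode: str = "midpoint"
    standardizer: Optional[Standardizer] = None
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    training_log: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.descriptor_names) != len(self.weights):
            raise ValueError("one weight per descriptor is required")
        if len(self.descriptor_names) == 0:
            raise ValueError("a model needs at least one descriptor")
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.threshold)):
            raise ValueError("weights and threshold must be finite")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ConfigError(f"threshold_mode must be one of {THRESHOLD_MODES}")

    def scores(self, matrix: DescriptorMatrix) -> np.ndarray:
        """f(C) for every compound, standardizing with the stored stats."""
        if self.standardizer is not None:
            matrix = self.standardizer.transform(matrix)
        else:
            matrix = matrix.subset(self.descriptor_names)
        return matrix.values @ self.weights

    def predict(self, matrix: DescriptorMatrix) -> np.ndarray:
        return classify_scores(self.scores(matrix), self.threshold)


def weighted_sum(weights: np.ndarray, x: np.ndarray) -> float:
    """The no-intercept score f(C) = sum_i w_i * x_i of one compound."""
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    if weights.shape != x.shape:
        raise ValueError(f"shape mismatch: {weights.shape} vs {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite descriptor value")
    return float(weights @ x)


def rss(weights: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the class codes against X @ weights."""
    weights = np.asarray(weights, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != weights.shape[0]:
        raise ValueError("weight length does not match descriptor count")
    residuals = y - X @ weights
    return float(residuals @ residuals)


def fit_initial_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Univariate least-squares slope of y on each descriptor column.

    Each w_i minimises the per-descriptor residual sum of squares
    sum_j (y_j - w * x_ij - b)^2 over (w, b); only the slope is kept, the
    no-intercept score relying on standardized (centred) descriptors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise DegenerateProblemError("need >= 2 compounds to fit slopes")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc * xc, axis=0)
    if np.any(sxx == 0.0):
        j = int(np.argmax(sxx == 0.0))
        raise DegenerateProblemError(
            f"descriptor column {j} has zero variance; standardize first"
        )
    return (xc.T @ yc) / sxx


def andrews_fitness(residuals: np.ndarray, a: float = ANDREWS_A_DEFAULT) -> float:
    """Negative total Andrews' sine loss of the residuals (higher = better).

    rho(r) = a^2 (1 - cos(r/a)) inside |r| <= pi a, constant 2 a^2 outside;
    rho(0) = 0, so a perfect fit attains the maximum fitness 0.
    """
    if a <= 0:
        raise ConfigError("the Andrews constant a must be > 0")
    r = np.abs(np.asarray(residuals, dtype=float))
    # a^2 (1 - cos(r/a)) = 2 a^2 sin^2(r/(2a)): exact, and numerically
    # stable for r/a << 1 where 1 - cos underflows
    s = np.sin(np.minimum(r, np.pi * a) / (2.0 * a))
    rho = 2.0 * a * a * s * s
    return float(-np.sum(rho))


def _fitness_batch(
    W: np.ndarray, X: np.ndarray, y: np.ndarray, config: OptimizerConfig
) -> np.ndarray:
    """Fitness of every weight vector in the (pop, M) array W."""
    residuals = y[None, :] - W @ X.T
    if config.fitness_kind == "sum_of_squares":
        return -np.sum(residuals * residuals, axis=1)
    a = config.andrews_a
    r = np.abs(residuals)
    s = np.sin(np.minimum(r, np.pi * a) / (2.0 * a))
    return -np.sum(2.0 * a * a * s * s, axis=1)


def optimize_weights_ga(
    X: np.ndarray,
    y: np.ndarray,
    initial_weights: np.ndarray,
    config: OptimizerConfig = OptimizerConfig(),
) -> tuple[np.ndarray, list[float]]:
    """Refine the weight vector with an elitist real-coded GA.

    The search box for gene i is ``w_i +/- h * s_i`` with
    ``h = search_halfwidth_sds`` and ``s_i = |w_i| + RMS(W_init)`` (1.0
    when the initialization is identically zero).  Generation 0 contains
    the initial weights, and elites are copied unchanged, so the returned
    best-ever chromosome can never score below the initialization.
    Offspring come from BLX-alpha blend crossover and per-gene Gaussian
    mutation, clipped to the box.  Deterministic given ``config.seed``.

    Returns the best-ever weight vector and the per-generation best-fitness
    trace.
    """
    w0 = np.asarray(initial_weights, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(w0)):
        raise ValueError("initial weights must be finite")
    M = w0.shape[0]
    if X.shape[1] != M:
        raise ValueError("initial weights do not match descriptor count")

    pooled = float(np.sqrt(np.mean(w0 * w0))) or 1.0
    scale = np.abs(w0) + pooled
    lo = w0 - config.search_halfwidth_sds * scale
    hi = w0 + config.search_halfwidth_sds * scale
    width = hi - lo

    init_fitness = float(_fitness_batch(w0[None, :], X, y, config)[0])
    if config.max_generations == 0:
        return w0.copy(), [init_fitness]

    rng = np.random.default_rng(config.seed)
    pop = config.population_size
    population = lo + rng.random((pop, M)) * width
    population[0] = w0
    fitness = _fitness_batch(population, X, y, config)

    best_idx = int(np.argmax(fitness))
    best_w = population[best_idx].copy()
    best_fit = float(fitness[best_idx])
    trace = [best_fit]
    stall = 0

    from .feature_selection import _rank_selection_probs

    for _ in range(config.max_generations):
        probs = _rank_selection_probs(fitness)
        elite_idx = np.argsort(-fitness, kind="stable")[: config.elitism_count]
        children = np.empty_like(population)
        children[: config.elitism_count] = population[elite_idx]
        n_rest = pop - config.elitism_count
        parents = rng.choice(pop, size=(n_rest, 2), p=probs)
        pa = population[parents[:, 0]]
        pb = population[parents[:, 1]]
        low = np.minimum(pa, pb)
        high = np.maximum(pa, pb)
        span = high - low
        u = rng.random((n_rest, M))
        blended = (
            low - config.blx_alpha * span
            + u * (1.0 + 2.0 * config.blx_alpha) * span
        )
        do_cx = rng.random(n_rest) < config.crossover_prob
        offspring = np.where(do_cx[:, None], blended, pa)
        mut = rng.random((n_rest, M)) < config.mutation_prob
        noise = rng.normal(0.0, config.mutation_sd_frac, size=(n_rest, M)) * width
        offspring = np.where(mut, offspring + noise, offspring)
        np.clip(offspring, lo, hi, out=offspring)
        children[config.elitism_count:] = offspring
        population = children
        fitness = _fitness_batch(population, X, y, config)
        gen_idx = int(np.argmax(fitness))
        if float(fitness[gen_idx]) > best_fit + 1e-12:
            best_fit = float(fitness[gen_idx])
            best_w = population[gen_idx].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_fit)
        if stall >= config.stall_generations:
            break

    return best_w, trace


def compute_threshold(
    scores: np.ndarray, labels: np.ndarray, mode: str = "midpoint"
) -> float:
    """Decision threshold from the training scores of the two classes.

    ``midpoint`` (default): (mean active score + mean inactive score) / 2.
    ``literal_difference``: mean active score - mean inactive score.
    """
    if mode not in THRESHOLD_MODES:
        raise ConfigError(f"threshold mode must be one of {THRESHOLD_MODES}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    active = scores[labels == ACTIVE]
    inactive = scores[labels == INACTIVE]
    if active.size == 0 or inactive.size == 0:
        raise DegenerateProblemError("both classes are needed for a threshold")
    if mode == "midpoint":
        return float((active.mean() + inactive.mean()) / 2.0)
    return float(active.mean() - inactive.mean())


def classify_scores(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Label 1 (active) where f(C) < threshold, else 2; ties go inactive."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores < threshold, ACTIVE, INACTIVE)


def train(
    dataset: LabeledDataset,
    descriptor_names: list[str],
    config: OptimizerConfig = OptimizerConfig(),
    threshold_mode: str = "midpoint",
    apply_standardization: bool = True,
) -> ELMModel:
    """Full training pass: standardize, initialise, refine, set threshold.

    ``descriptor_names`` is the selected subset (from a SelectionResult or
    given explicitly).  Standardization statistics are fitted on this
    training data only and stored on the model for later prediction.
    """
    if len(descriptor_names) == 0:
        raise DegenerateProblemError("cannot train on an empty descriptor subset")
    counts = dataset.class_counts()
    if min(counts) == 0:
        raise DegenerateProblemError("both classes are required for training")
    sub = dataset.matrix.subset(list(descriptor_names))
    if apply_standardization:
        Z, stats = standardize(sub)
        if stats.dropped_names:
            logger.info(
                "train: dropped constant descriptor(s) %s", stats.dropped_names
            )
    else:
        Z = sub
        stats = Standardizer(
            list(sub.descriptor_names),
            np.zeros(sub.n_descriptors),
            np.ones(sub.n_descriptors),
        )
    X = Z.values
    y = dataset.y
    w0 = fit_initial_weights(X, y)
    w_opt, trace = optimize_weights_ga(X, y, w0, config)
    scores = X @ w_opt
    threshold = compute_threshold(scores, dataset.labels, threshold_mode)
    initial_rss = rss(w0, X, y)
    final_rss = rss(w_opt, X, y)
    logger.info(
        "train: RSS %.4f -> %.4f over %d generations",
        initial_rss, final_rss, len(trace) - 1,
    )
    return ELMModel(
        descriptor_names=list(Z.descriptor_names),
        weights=w_opt,
        threshold=threshold,
        threshold_mode=threshold_mode,
        standardizer=stats,
        seed=config.seed,
        config={
            "population_size": config.population_size,
            "mutation_prob": config.mutation_prob,
            "max_generations": config.max_generations,
            "fitness_kind": config.fitness_kind,
            "andrews_a": config.andrews_a,
            "search_halfwidth_sds": config.search_halfwidth_sds,
            "elitism_count": config.elitism_count,
        },
        training_log={
            "initial_weights": w0.tolist(),
            "initial_rss": initial_rss,
            "final_rss": final_rss,
            "fitness_trace": trace,
        },
    )


def train_initial(
    dataset: LabeledDataset,
    descriptor_names: list[str],
    threshold_mode: str = "midpoint",
) -> ELMModel:
    """Baseline model using the least-squares initialization only."""
    cfg = OptimizerConfig(max_generations=0)
    return train(dataset, descriptor_names, cfg, threshold_mode)
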