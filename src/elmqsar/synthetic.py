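"""Synthetic descriptor tables with planted class structure.

Real descriptor tables for aromatase inhibitors pair a few hundred
compounds with several hundred correlated molecular descriptors, of which
only a small subset carries the activity signal.  The generator emulates
that shape with the simplest recoverable structure: class-conditional
Gaussian informative descriptors whose class means differ by
``effect_size`` within-class standard deviations on average — individual
descriptors span ``effect_size * (1 -/+ effect_heterogeneity)``, because
real descriptors differ widely in relevance — equicorrelated within the
informative block (molecular descriptor blocks are collinear), plus
independent standard-normal noise descriptors.  Under this design a
no-intercept linear score on standardized descriptors with a midpoint
threshold is Bayes-consistent, so parameter-recovery and
selection-recovery tests have a ground truth to recover.  Heterogeneous
effects and within-block correlation also make the univariate
least-squares initialization genuinely suboptimal relative to the joint
optimum, which is the regime the GA refinement stage exists for; with
homogeneous uncorrelated effects the initialization already points along
the joint optimum and refinement has nothing systematic to improve.

Class sizes are allocated deterministically (``round(active_fraction *
n)`` actives), not by Bernoulli draws, so fixtures with exact class
counts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .data_model import ACTIVE, INACTIVE, DescriptorMatrix, LabeledDataset
from .errors import ConfigError


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults emulate a mid-sized QSAR campaign: 300 compounds, 100
    candidate descriptors of which 10 are informative with a standardized
    class-mean difference of 1.0, and a 45% active fraction (the class
    imbalance typical of curated inhibitor sets).
    """

    n_compounds: int = 300
    n_descriptors: int = 100
    n_informative: int = 10
    effect_size: float = 1.0
    effect_heterogeneity: float = 0.5
    active_fraction: float = 0.45
    descriptor_correlation: float = 0.3
    noise_sd: float = 1.0
    pic50_mode: bool = False
    intermediate_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ConfigError("n_informative cannot exceed n_descriptors")
        if not 0.0 < self.active_fraction < 1.0:
            raise ConfigError("active_fraction must be in (0, 1)")
        if not 0.0 <= self.descriptor_correlation < 1.0:
            raise ConfigError("descriptor_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_compounds < 4 or self.n_descriptors < 1:
            raise ConfigError("need >= 4 compounds and >= 1 descriptor")
        if not 0.0 <= self.intermediate_fraction < 1.0:
            raise ConfigError("intermediate_fraction must be in [0, 1)")
        if not 0.0 <= self.effect_heterogeneity < 1.0:
            raise ConfigError("effect_heterogeneity must be in [0, 1)")
        n_active = int(round(self.active_fraction * self.n_compounds))
        if n_active < 2 or self.n_compounds - n_active < 2:
            raise ConfigError("each class needs >= 2 compounds")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``effect_sizes`` holds each informative descriptor's planted
    standardized class-mean difference (inactive mean minus active mean,
    in within-class sd units); ``true_weights`` the population univariate
    slope of the class code on each informative descriptor.
    """

    informative_names: list[str]
    effect_sizes: dict[str, float]
    true_weights: dict[str, float]
    bayes_accuracy: float
    n_active: int
    n_inactive: int

    def to_dict(self) -> dict:
        return {
            "informative_names": self.informative_names,
            "effect_sizes": self.effect_sizes,
            "true_weights": self.true_weights,
            "bayes_accuracy": self.bayes_accuracy,
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
        }


def _informative_block(
    rng: np.random.Generator,
    n: int,
    m: int,
    rho: float,
    sd: float,
) -> np.ndarray:
    """n x m draws from N(0, Sigma), Sigma = sd^2 [(1-rho) I + rho J]."""
    z = rng.standard_normal((n, m))
    if rho == 0.0 or m == 1:
        return sd * z
    shared = rng.standard_normal((n, 1))
    return sd * (np.sqrt(1.0 - rho) * z + np.sqrt(rho) * shared)


def generate(config: SyntheticConfig) -> tuple[LabeledDataset, GroundTruth]:
    """Draw a labeled descriptor table with planted informative structure.

    Informative descriptor i has its class means separated by
    ``delta_i * noise_sd`` where the delta_i are evenly spaced over
    ``effect_size * [1 - h, 1 + h]`` (h = ``effect_heterogeneity``), mean
    ``effect_size``.  Active compounds sit ``delta_i / 2`` below centre,
    inactives the same amount above (actives score low, matching the
    class codes 1 < 2).  Noise descriptors are class-independent standard
    Gaussians.  In pIC50 mode actives get pIC50 = 6 + margin, inactives
    5 - margin (margin ~ |N(0, 0.5)|), and an ``intermediate_fraction``
    of compounds fall uniformly inside (5, 6) with mean-zero descriptors,
    exercising the curation step.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    p = config.n_descriptors
    m = config.n_informative
    n_active = int(round(config.active_fraction * n))
    n_inactive = n - n_active

    labels = np.concatenate(
        [np.full(n_active, ACTIVE), np.full(n_inactive, INACTIVE)]
    )
    intermediate = np.zeros(n, dtype=bool)
    pic50 = None
    if config.pic50_mode:
        n_mid = int(round(config.intermediate_fraction * n))
        mid_idx = rng.choice(n, size=n_mid, replace=False)
        intermediate[mid_idx] = True
        margin = np.abs(rng.normal(0.0, 0.5, size=n))
        pic50 = np.where(labels == ACTIVE, 6.0 + margin, 5.0 - margin)
        pic50[intermediate] = rng.uniform(5.0, 6.0, size=n_mid)

    h = config.effect_heterogeneity
    if m > 1:
        deltas = config.effect_size * np.linspace(1.0 - h, 1.0 + h, m)
    else:
        deltas = np.full(m, config.effect_size)
    # class-conditional means on the informative block; intermediates sit at 0
    sign = np.where(labels == ACTIVE, -0.5, 0.5).astype(float)
    sign[intermediate] = 0.0

    values = rng.standard_normal((n, p))
    if m > 0:
        block = _informative_block(
            rng, n, m, config.descriptor_correlation, config.noise_sd
        )
        values[:, :m] = (
            sign[:, None] * deltas[None, :] * config.noise_sd + block
        )

    order = rng.permutation(n)
    labels = labels[order]
    values = values[order]
    if pic50 is not None:
        pic50 = pic50[order]

    width = max(3, len(str(p)))
    names = [f"D{j + 1:0{width}d}" for j in range(p)]
    ids = [f"CMP{i + 1:04d}" for i in range(n)]
    dataset = LabeledDataset(
        DescriptorMatrix(ids, names, values), labels, pic50
    )

    informative = names[:m]
    # per-descriptor population slope of the class code on the descriptor:
    # class-mean gap delta_i * sd; mixture variance sd^2 + f(1-f) gap^2
    f = n_active / n
    gaps = deltas * config.noise_sd
    var = config.noise_sd**2 + f * (1 - f) * gaps**2
    slopes = f * (1 - f) * gaps / var  # cov(x, y)/var(x), y in {1, 2}
    true_weights = {d: float(s) for d, s in zip(informative, slopes)}
    # Bayes accuracy for the Gaussian mixture: Phi(d_M / 2), d_M the
    # Mahalanobis distance between class means under the equicorrelated
    # covariance Sigma = sd^2 [(1-rho) I + rho J]
    if m > 0:
        rho = config.descriptor_correlation
        d2 = (
            gaps @ gaps - rho * gaps.sum() ** 2 / (1.0 - rho + m * rho)
        ) / (config.noise_sd**2 * (1.0 - rho))
        bayes = float(sps.norm.cdf(np.sqrt(d2) / 2.0))
    else:
        bayes = max(f, 1 - f)
    truth = GroundTruth(
        informative_names=informative,
        effect_sizes={d: float(g) for d, g in zip(informative, deltas)},
        true_weights=true_weights,
        bayes_accuracy=bayes,
        n_active=int(np.sum(dataset.labels == ACTIVE)),
        n_inactive=int(np.sum(dataset.labels == INACTIVE)),
    )
    return dataset, truth


# --- worked example ------------------------------------------------------

_WORKED_Y = [1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2]
# SLOPE1 = y - 1.5 (slope exactly 1); SLOPE2 = -(y - 1.5)/2 (slope -2);
# NOISE1/NOISE2 sum to zero within each class, so their covariance with y
# is exactly zero and their least-squares slope is 0.
_WORKED_COLUMNS = {
    "SLOPE1": [-0.5, -0.5, -0.5, -0.5, -0.5, -0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
    "SLOPE2": [0.25, 0.25, 0.25, 0.25, 0.25, 0.25, -0.25, -0.25, -0.25, -0.25, -0.25, -0.25],
    "NOISE1": [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0],
    "NOISE2": [1.0, 1.0, -1.0, -1.0, 2.0, -2.0, -1.0, 1.0, 1.0, -1.0, -2.0, 2.0],
}


def generate_worked_example() -> tuple[LabeledDataset, dict[str, float]]:
    """A tiny constant dataset (n=12, p=4) with hand-computable slopes.

    SLOPE1 and SLOPE2 are exact linear functions of the class code with
    least-squares slopes 1 and -2; NOISE1 and NOISE2 are orthogonal to the
    class code (slope exactly 0).  Byte-identical on every call.
    """
    names = list(_WORKED_COLUMNS)
    values = np.array([_WORKED_COLUMNS[d] for d in names]).T
    ids = [f"WX{i + 1:02d}" for i in range(len(_WORKED_Y))]
    dataset = LabeledDataset(
        DescriptorMatrix(ids, names, values), np.array(_WORKED_Y)
    )
    expected_slopes = {"SLOPE1": 1.0, "SLOPE2": -2.0, "NOISE1": 0.0, "NOISE2": 0.0}
    return dataset, expected_slopes
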