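# Methods

## The model

A compound C with descriptor values x₁…x_M (z-scored with statistics
fitted on the training compounds) is scored by the no-intercept weighted
sum f(C) = Σᵢ wᵢxᵢ and classified against a scalar threshold t: active
(code 1) when f(C) < t, inactive (code 2) otherwise, ties going to
inactive. The class codes double as the regression response y ∈ {1, 2},
which fixes the sign convention: descriptors elevated in actives get
negative weights, so active compounds score low. Because every
descriptor is centred, f has mean zero on the training set regardless of
W; the model carries no intercept and relies on the threshold to place
the decision boundary.

The linear form is an assumption, not a discovery: the package targets
regimes (a few hundred compounds, collinear descriptor blocks) where a
sparse linear score with a robust fit is competitive and every term is
interpretable.

## Descriptor selection

Selection composes two stages with different jobs:

- **Welch t-test prefilter** (two-sided, unequal variances, default
  α = 0.001). Per-descriptor tests do not depend on which other
  descriptors are in a subset, so they are applied once, before the
  search, rather than folded into the subset fitness. Descriptors
  constant in both classes get p = 1. At α = 0.001 a pure-noise
  descriptor survives with probability ≈ α, so a 600-descriptor pool
  contributes well under a handful of false survivors.
- **Binary-chromosome GA** over the survivors, fitness −AIC with
  AIC = n·ln(RSS/n) + 2(k+1) from the OLS fit (with intercept) of the
  class codes on the k included descriptors. RSS is floored at 1e-12 so
  a perfect fit stays finite; a collinear subset falls back to a tiny
  ridge (1e-8) rather than failing mid-search.

GA operators: linear rank-scaled fitness-proportional selection, uniform
crossover (rate 0.8), per-bit mutation at 0.03, two elites copied
unchanged, all-zero chromosomes repaired to a random single bit.
Population 100, generation cap 1000, early stop after 200 generations
without improvement of the best fitness (the cap is a ceiling, not a
requirement). Only mutation rate, population size and the generation cap
are externally fixed conventions; the remaining operator choices are
this package's and are exposed in `SelectionConfig`.

**Usage frequency** — the number of chromosomes in the *final*
generation containing a descriptor — is the importance measure (0 to
population size). The final population is used because it reflects the
converged preference; a cumulative average over all generations is
available behind `cumulative_usage` for smoother but less decisive
rankings. The selected subset is every descriptor with usage ≥
`usage_cutoff` (default 90 under a population of 100), sorted by usage
then name; when the cutoff admits nothing, the pipeline falls back to
the top-10 ranking rather than aborting.

## Weight fitting

Initial weights are the per-descriptor univariate least-squares slopes
of y. This deliberately ignores correlation between descriptors — it is
an O(np) closed form, and its crudeness is the point: the refinement
stage exists to repair exactly the double counting the univariate view
commits on collinear blocks.

Refinement is a real-coded GA maximising the negative total Andrews'
sine loss of the residuals r = y − f(C):

    ρ(r) = a²(1 − cos(r/a))  for |r| ≤ πa,   2a² otherwise

implemented as 2a²·sin²(r/2a), which is algebraically identical and
numerically stable when r/a is tiny (the 1 − cos form loses all
precision by a ≈ 10⁶, where the loss must approach r²/2). The
redescending shape caps any single compound's influence at 2a², so a few
mislabeled or atypical compounds cannot dominate the fit; a = 1.339 is
the conventional 95%-efficiency constant and is exposed in
`OptimizerConfig`, as is a plain −RSS fitness (`sum_of_squares`).

GA details: genes live in the box wᵢ ± 5sᵢ with sᵢ = |wᵢ| + RMS(W₀)
(an unbounded real GA is ill-posed; the box is generous relative to the
initialization and configurable); BLX-0.5 blend crossover; per-gene
Gaussian mutation with sd = 10% of the box width at rate 0.03; rank
selection; 2 elites; the initial weight vector seeded into generation 0.
Elitism plus the seeded chromosome give a hard guarantee: the returned
best-ever vector never scores below the initialization on the GA's own
objective. Stopping mirrors the selection GA (1000-generation cap, 200
stagnant-generation patience).

## Threshold

Two modes:

- **midpoint** (default): t = (mean f over actives + mean f over
  inactives)/2. For separated score distributions this lies between
  them, and under the generator's symmetric Gaussian design it is the
  Bayes cut on the score axis.
- **literal_difference**: t = mean(f | active) − mean(f | inactive).
  This is the difference-of-class-means rule stated verbatim in some
  descriptions of the approach. A difference of means generally does
  *not* lie between the two score distributions (for centred scores it
  is negative whenever actives score low), so used naively it classifies
  almost everything as inactive. It is retained as an explicit mode for
  fidelity experiments, not as a sensible default — a loud documented
  choice.

## Evaluation protocol

Sen, Spec and Acc are reported as percentages; MCC in [−1, 1], defined
as 0 whenever its denominator vanishes (a degenerate margin carries no
correlation information; the convention avoids NaN propagation). MCC
equals the Pearson correlation of the binary indicator vectors, which
the tests assert on random instances.

Cross-validation is stratified by class — the stated protocol is a plain
random split, but with imbalanced classes an unstratified fold can lose
one class entirely, and a threshold cannot be computed without both.
Every fold's model is fitted from scratch (standardization included) on
the other k−1 folds. Both pooled metrics (confusion counts summed over
validation folds) and the per-fold average are reported; descriptor
selection runs once outside CV by default (matching the protocol the
package emulates, which selects on the full data), and a nested mode
re-runs selection inside every training fold for leakage-free
estimates — the honest-but-slower option.

`repeat_experiments` reruns train + k-fold CV R times (default 10) with
consecutive seeds, re-randomising both the GA and the folds each run,
and reports per-run rows plus mean ± sample sd, identifying the best run
by pooled CV MCC.

## Synthetic data

The generator plants a recoverable truth in the simplest structure the
model can represent optimally: informative descriptors are
class-conditional Gaussians whose class means differ by δᵢ within-class
sds, noise descriptors are independent standard normals, and labels are
allocated deterministically (round(active_fraction·n) actives) so
fixtures are exactly reproducible. Defaults — 300 compounds, 100
descriptors, 10 informative, active fraction 0.45 — emulate a mid-sized
binary QSAR campaign with moderate class imbalance.

Two defaults deserve justification:

- **Heterogeneous effects** (δᵢ spread evenly over effect_size·[0.5,
  1.5], mean = effect_size): real descriptors differ widely in
  relevance, and with *equal* effects the univariate initialization
  already points along the joint optimum, making the refinement stage
  untestable — any change it makes is pure noise.
- **Equicorrelated informative block** (ρ = 0.3): molecular descriptor
  families are collinear. Correlation is what makes per-descriptor
  slopes jointly miscalibrated, i.e. what gives refinement systematic
  work to do.

In pIC50 mode, actives get 6 + |N(0, 0.5)| and inactives 5 − |N(0, 0.5)|,
with a configurable fraction of compounds placed uniformly inside (5, 6)
and given mean-zero descriptors, exercising the curation rule below.

What the generator does **not** emulate: heavy-tailed or discrete
descriptor distributions, block structure beyond one equicorrelated
clique, activity cliffs, label noise, or any chemistry-derived
constraint between descriptors. Passing tests therefore demonstrate
correct mechanics and sane statistical behaviour under a Gaussian
mixture — not predictive performance on real inhibitor data.

## Curation

Compounds with pIC50 strictly inside (5, 6) are removed as intermediate;
pIC50 ≥ 6 is active, ≤ 5 inactive. The boundary handling (keep exact
5.0 and 6.0) is this package's choice — the convention the rule derives
from does not state inclusivity — picked to keep boundary compounds and
stay deterministic. Both bounds are configurable (`CurationRule`).

## Numerical and degenerate-input choices

- z-scoring uses the sample sd (ddof = 1); zero-variance columns are
  excluded with a record, since a constant descriptor has no defined
  slope. Statistics are fitted on training data only and stored on the
  model, making predictions invariant to the raw units of new data.
- Model files are flat key–value text; floats serialize via `repr`
  (shortest exact decimal), so save → load is bit-identical.
- Strict CSV loading names the first offending cell; permissive mode
  drops offending descriptor *columns*, never compounds — compounds are
  the scarce resource.
- All stochastic components consume a `numpy.random.Generator` seeded
  explicitly; the pipeline spawns per-stage seeds from one master seed
  via `SeedSequence([master, stage_index])` reduced mod 2³¹, so one
  integer reproduces a full run byte-for-byte (timestamps in the log
  aside).
- Test-suite and acceptance-script problem sizes (300×100 datasets,
  10 seeds, 10×10-fold CV) are chosen as the smallest conditions at
  which selection recovery, refinement gain and CV stability are
  clearly measurable.

## Known limitations

- No intercept and a single threshold mean the model cannot express
  class-conditional variance differences; it is a linear discriminant
  in spirit and inherits its failure modes.
- AIC on the 1/2 class codes treats classification as regression; it is
  faithful to the method's design but is not a proper classification
  likelihood.
- Default (non-nested) CV inherits the selection-outside-CV optimism of
  the emulated protocol; use nested mode for unbiased estimates.
- The selection GA's usage frequencies are a population statistic, not a
  probability; they depend on population size, convergence and the
  usage-count convention (final vs cumulative).
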