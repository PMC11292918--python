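# Methods

## The model

Matched case–control data come in *n* strata of size m_i: one case
(y_ij = 1) and its matched controls (y_ij = 0).  The working model is a
conditional logistic regression

    logit P(y_ij = 1) = alpha_i + x_ij * beta + f(z_ij),

where alpha_i are stratum effects, x is an optional dedicated binary
exposure with log odds ratio beta, and f describes the covariate
effect.  Conditioning on "exactly one case per stratum" eliminates the
alpha_i: each stratum's contribution becomes a softmax

    P(case is row j* | stratum) = exp(eta_{ij*}) / sum_j exp(eta_{ij}),

so the likelihood is invariant to any stratum-constant shift of the
linear predictor.  Nothing in the package ever stores or estimates an
alpha_i.

Three choices of f are implemented:

* **CLR** — f(z) = z' gamma (the standard linear model; CLR0 drops the
  covariates altogether).
* **CLogitTree** — f(z) = sum_t delta_t I(z in S_t), a step function
  over the terminal nodes of a binary tree, grown by best-first search
  on the penalized conditional log-likelihood.
* **CLogitForest** — an ensemble of such trees grown on stratum-level
  resamples with mtry split-variable randomization; predictions are the
  average of the per-tree linear predictors and the exposure estimate
  is the arithmetic mean of the per-tree beta.

## Estimation

All fitting reduces to one routine: a Newton maximizer of the
ridge-penalized conditional log-likelihood with analytic gradient
`X'(y - p)` and Fisher information `X' diag(p) X - S'S` (S the matrix
of per-stratum probability-weighted column means), step-halving line
search, and convergence when the relative objective change falls below
1e-10 or the gradient max-norm below 1e-8 (iteration cap 100).  The
ridge weight defaults to lambda = 1e-20 on all coefficients — just
enough to keep the optimum finite under perfect within-stratum
separation; a guard additionally caps coefficients at +-50 on the
log-odds scale and flags the fit.  Because a full set of terminal-node
indicators sums to one, the information matrix has an exactly flat
direction (a common shift of all delta); Newton steps are therefore
taken as minimum-norm least-squares solutions whenever lambda is
negligible, and the fitted delta are re-centered to mean zero after
every refit.  Both operations change no predicted probability.

### Tree growth

Growth is global best-first: starting from the stratum intercepts
(plus the exposure effect, if any), each iteration draws a fresh random
subset of `mtry` covariates, enumerates midpoint thresholds for every
(terminal node, subset variable) pair, and accepts the single best
split — judged by the gain in the penalized conditional log-likelihood
after a joint refit of all delta and beta — provided the gain exceeds
`epsilon` (default 1e-8) and the size constraints hold.  Ties are
broken toward the lower node id, then lower variable index, then
smaller threshold, so growth is fully deterministic given the seed.

Two candidate-scoring modes exist.  `exact` refits every candidate
jointly (warm-started at the incumbent); `fast` ranks candidates by
optimizing only the two prospective child effects with everything else
fixed — a two-parameter Newton solved simultaneously for all
thresholds of a variable — and then refits the winner jointly, deciding
acceptance on its exact gain.  Standalone trees default to `exact`;
forest base learners default to `fast`, which makes 500-tree ensembles
tractable (measured ~25x faster per tree) while the accept/stop
decision itself remains the exact likelihood gain.

### Node-size defaults

`min_split_n` and `min_bucket_n` are counted in rows, but their
defaults resolve to 20 and 7 *matched sets' worth* of rows (20/7 times
the mean stratum size; 80/28 rows at 1:3 matching).  The rationale:
each stratum contributes a single multinomial term to the conditional
likelihood, so the effective sample size of a node is the number of
matched sets it touches, not its row count.  Row-count defaults of
20/7 let base learners approach within-stratum separation, and the
jointly refit exposure effect then inherits the classical sparse-strata
(Neyman–Scott-type) inflation of conditional-logit estimates — in our
experiments per-tree beta drifted to several times the truth while
predictions remained good.  With stratum-scaled defaults the per-tree
exposure estimate stays close to the CLR estimate while forests retain
enough capacity to beat CLR on tree-structured truth once a few hundred
strata are available.  `max_depth` is unlimited by default; the size
constraints are what stop growth.

### BIC pruning (standalone trees only)

Standalone trees are pruned to the prefix of the growth sequence
minimizing BIC = -2 * conditional log-lik + df * log(n) with
df = (terminal nodes - 1) + 1(exposure); the -1 reflects the flat
shift direction of the delta.  Trees inside a forest are never pruned.
BIC pruning reliably removes noise splits on low-cardinality (binary /
ordinal) covariates; for continuous covariates the winner-take-all
selection over hundreds of candidate thresholds inflates in-sample
gains beyond a one-parameter-per-node count, so occasional surviving
noise splits are expected — a known limitation of information-criterion
pruning, shared with other greedy likelihood trees.

### Forest machinery

Resampling operates on whole strata: either an n-out-of-n bootstrap
(a stratum drawn twice contributes its likelihood term twice) or — the
default — a 63.2% subsample without replacement, matching the expected
unique fraction 1 - 1/e of the bootstrap while avoiding duplicate
strata.  Each tree gets an independent seed substream spawned from the
master seed, so fits are identical for any worker count.  Out-of-bag
(OOB) predictions average, per stratum, only trees whose resample
excluded that stratum; the mean OOB predictive conditional likelihood
is the internal model-quality criterion, used in particular to tune
mtry over {2..p} (ties to the smaller value; default 50 trees per
candidate).  With the linear-offset option, a CLR on the full training
data is fitted first and z' gamma-hat (exposure excluded) enters every
tree as a fixed per-row offset, so splits only model what the linear
fit leaves unexplained; on exactly linear truth the within-tree
likelihood gain from splitting roughly halves, though trees still fit
some noise (any best-of-many candidate split clears epsilon).

Aggregation averages per-tree *linear predictors* (log-odds scale),
consistent with averaging beta; averaging per-stratum probabilities is
available as an option.

## Interpretation

**Permutation importance** measures, per covariate, the drop in the
mean per-stratum predictive conditional likelihood after shuffling that
covariate's column across all rows (within-stratum shuffling is an
option); predictions are re-evaluated, nothing is refitted.  The `oob`
variant (default, more robust to overfitting) restricts each tree's
comparison to its own OOB strata and averages per-tree differences;
`all_obs` compares whole-forest predictions on all strata, averaged
over nperm = 5 permutations (1 for `oob`, where per-tree averaging
already smooths).  A variable used in no split of an offset-free
forest scores exactly zero.  When a linear offset is present, the
permuted column also enters the offset, so linear-only effects are
credited too.

**Bootstrap confidence intervals** for beta re-apply the entire forest
procedure (including mtry re-tuning if configured) to B stratum-level
bootstrap resamples and report empirical percentile bounds of the B
averaged estimates.  Quantiles use the inverse-CDF order-statistic
convention without interpolation — at B = 50 and level 0.95 the bounds
are the 2nd smallest and 2nd largest draws — because at small B the
convention visibly moves the interval.

## The synthetic-study generator

The generator emulates a district-matched design: `population` persons
are distributed uniformly over `n_districts` districts; each district j
carries two effects tau_j (disease) and tau_j^x (exposure), both
uniform on [-2, 2]; persons carry p standard-normal characteristics, of
which the first two signal variables are dichotomized at 0 (the
population median).  Exposure follows
logit P(x=1) = c0 + sum_k a_k z_k + tau^x with a_k = +-0.2 alternating
over the signal variables (making them confounders); disease follows
logit P(y=1) = -2 + tau + log(2) * x + f_k(z).  Three outcome families:

* **A** (linear): f = sum of +-0.4 z over signal variables, alternating
  sign.
* **B** (tree): the sum of two depth-2 step functions over signal
  variables 1–4, node values in {-0.8, 0, +0.8} (at most 9 distinct
  values of f).
* **C** (smooth): sin(pi z), (z^2 - 1), tanh(z) applied cyclically to
  the signal variables, each standardized to unit variance on
  standard-normal input and scaled by 0.4 so per-variable contributions
  match setting A.

The identities and order of the signal variables are re-permuted in
every replication, so the concrete truth differs between rounds.
Exposure-model and f-coefficients above are this package's declared
defaults for the stated functional families; all are overridable in
`DGPConfig`.  A matched study then samples `n_strata` cases from the
diseased without replacement and matches each to
`controls_per_case` non-diseased persons of the same district, never
reusing a person; the validation study is an independent second sample
from the same population sharing no person with the training study.

Two scales are built in: `DGPConfig.paper()` (population 500 000,
1000 districts, 400 strata) and `DGPConfig.reduced()`
(population 20 000, 100 districts, 100 strata), the scale used
throughout the tests and the acceptance script.  Quality measures: the
mean per-stratum predictive conditional likelihood on the validation
study, and the absolute error of the log exposure effect.

### What the generator does and does not emulate

It reproduces the design features that matter for the method: strata
formed by a high-cardinality matching variable, confounding of exposure
by both covariates and the matching variable, 1:m matching, and
linear / tree / smooth covariate effects.  It does not emulate
measurement error, missing data, ordinal covariates with irregular
spacing, informative matching-variable selection, or overlap of cases
across districts — so passing tests demonstrate correctness of the
machinery and qualitative method behavior, not performance guarantees
on any particular real study.

## Problem sizes used in tests and the acceptance script

Replication studies run at the reduced scale (population 20 000,
100 districts): n = 100 strata for parameter-recovery runs (50
replications) and n = 200 strata for the method-ordering runs (20
replications, 100-tree forests, fixed mtry = 5), with 25-tree offset
forests for recovery.  At n = 100 the stratum-scaled node sizes leave
base learners too little capacity for the tree-structured truth of
setting B, which is why the ordering runs use n = 200; these sizes are
the package's chosen defaults for its own validation studies.

## Known limitations

* Strata with more than one case are not supported (the conditional
  likelihood would need combinatorial sums).
* Missing covariate values are rejected, not imputed.
* Unordered categoricals with >2 levels are not supported; ordinals
  enter as consecutive integer codes.
* The per-tree exposure estimate inherits some upward finite-sample
  bias from overfitting base learners; the stratum-scaled node sizes
  bound it but do not remove it.  The forest estimate is therefore
  expected to sit slightly above the CLR estimate, most visibly
  without the linear offset.
* BIC pruning under-penalizes continuous-threshold selection (above).
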