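# Methods

## Problem and model

Wrapper feature selection treats subset choice as a black-box minimization:
a candidate mask over the `D` features is scored by the cross-validated
error of a classifier restricted to the selected columns, and a search
heuristic explores the `2^D` mask space. `gwofs` implements that search
with the grey wolf optimizer family. Wolves carry *continuous* positions in
`[0,1]^D`; the binary mask exists only through the sigmoid transfer
function. This keeps the well-studied continuous GWO update intact and
confines discretization to a single stochastic thresholding step.

## The search loop

Iterations are 1-based, `t = 1..T`. The initial population is uniform in
`[0,1]^D` and evaluated once before the loop; each iteration then updates
all positions, binarizes, evaluates (`n` evaluations per iteration — no
mechanism adds more), refreshes the leaders from the current population,
and updates an elitist best-so-far that never worsens. The reported trace
is the best-so-far error per iteration and is nonincreasing by
construction.

Ranking and ties: candidates are ordered by ascending error; at equal
error, by smaller subset; at equal error and size, by agent index. The
secondary subset-size key is our choice where the underlying formulation is
silent. It matters in easy regimes: once many masks reach the same (often
zero) error, a pure-error ranking gives the search no direction, while the
size key steers it toward compact subsets whose zero error can only be
sustained by genuinely informative features. This matches the usual
wrapper-FS convention that at equal accuracy the smaller subset wins, and
it applies identically to every variant, so ablation comparisons stay fair.

Positions are clipped to `[0,1]` once, after guide combination — a single
canonical projection point; mutated guides are intentionally not re-clipped
first. Out-of-range iteration values raise.

## Mechanisms

- **APC.** `a(t) = 2 − 2 sin((π/2)(t/T)³)`, evaluated on the ratio
  `t/T ∈ (0,1]`; the ratio-0 endpoint (value 2) exists as the analytic
  limit. The factor exceeds the linear ramp `2(1 − t/T)` everywhere below
  the schedules' crossover (`r ≈ 0.88`), i.e. exploration persists for
  ~88% of the run.
- **AFDB.** Scores every candidate `S = normF + normDP`, where `normF`
  min-max-normalizes fitness with the *lowest* error mapping to 1 (errors
  are minimized, so raw values are inverted before summing) and `normDP`
  min-max-normalizes the Euclidean distance to the best-so-far position
  ascending. A zero range maps that term to 0 for all candidates. The
  highest-scoring individual (ties: lowest index) replaces the wolf's own
  position as the encircling reference on odd iterations; even iterations
  use the wolf's own position. With 1-based counting the first iteration is
  odd, so FDB guidance acts immediately. The best agent participates in
  scoring (its distance term is 0, so it rarely wins).
- **ADV.** Guide `X_k` moves to `X_k + (X_best − X_k) ∘ ε` with standard
  normal `ε`, drawn per dimension and independently per guide (a
  scalar-per-guide mode is available via `scalar_mutation_noise` for
  sensitivity checks). The perturbation is mean-zero and proportional to
  the offset from the best-so-far, so mutation intensity adapts
  automatically. `X_best` is the elitist best-so-far, which can differ from
  the current α.

## Fitness

`cv_error` uses stratified k-fold assignment from scikit-learn with a fold
seed fixed once per run, so within a run fitness is a pure function of the
mask and all wolves are scored on identical partitions. The effective fold
count is `min(folds, L, smallest class count)`, keeping tiny fixtures
usable. KNN prediction itself is a vectorized squared-distance-matrix
computation: training rows are pre-sorted by class so a stable distance
sort resolves neighbour ties in favour of the lowest class, and vote ties
resolve to the lowest class via the count-table argmax. Defaults: `k = 5`
neighbours, 10 folds, no feature scaling (expression benchmarks arrive
provider-normalized); z-scoring fit on training folds only is available
behind `scale=True`. Binarization draws a fresh `r` per dimension per call;
each position is binarized once per iteration and the mask cached, so
bookkeeping never re-randomizes fitness. An all-zero mask is repaired to
one uniformly random bit.

## Randomness and reproducibility

One master seed spawns independent substreams (numpy `SeedSequence`) for
initialization, step coefficients, binarization, mutation, and fold
assignment. Sweeps derive per-run seeds as a pure hash of (master seed,
dataset index, algorithm index, run index), all below 2^31; reruns are
byte-identical up to wall-clock fields.

## Synthetic data

`make_microarray` emulates the high-dimension / small-sample regime:
Gaussian features with equal spherical covariance, class sizes as equal as
possible, and a planted subset of informative features whose
class-conditional means are spaced `class_sep · noise_sd` apart with a
random per-feature sign; all other features are label-independent noise.
Defaults (`L=60, D=200, 10 informative, C=2, sep=3, sd=1`) give a problem
that KNN solves once informative features dominate the mask, yet whose
truth set occupies only 5% of the columns — appropriate for recovery
scoring. The ground-truth indices are returned separately from the
dataset, so the optimizer stays blind to them.

What the generator does *not* model: gene–gene correlation structure,
batch effects, heavy-tailed intensities, class imbalance. Passing recovery
tests therefore demonstrates correct search dynamics under a clean planted
model, not performance on real microarrays.

`make_worked_fixture` is a deterministic 20×6 two-class dataset: feature 0
separates the classes with a 0.5 margin (class 0 in [0.05, 0.25], class 1
in [0.75, 0.95]), features 1–5 are uniform noise. All masks reaching zero
CV error contain feature 0, and noise-only masks err at ≥0.2, so "solved"
is unambiguous.

## Evaluation battery

Best/Worst/Mean follow the error orientation (min is best); Std uses the
H−1 denominator. Algorithm pairs are compared per dataset with the
two-sided Wilcoxon rank-sum test (exact enumeration when `n_a + n_b ≤ 12`
with no ties, otherwise the normal approximation with tie correction;
α = 0.05, no multiple-testing correction). Friedman mean ranks use
within-row average ranks (row sums conserve `k(k+1)/2`); the chi-square
statistic is computable but mean ranks are the primary output. Convergence
curves aggregate per-run traces by pointwise mean.

## Problem sizes in the test suite

The suite runs the full prescribed recovery setting (60×200, `n=30`,
`T=100`, 10 seeds, AMGWO and GWO side by side) — about half a minute —
plus oracle-equivalence sweeps (100 random FDB populations, 50 random KNN
instances, all no-tie rank-sum sizes ≤ 10) and the 20×6 fixture at
`n=10, T=30` over 10 seeds. Unit and property tests use small instances
(`L ≤ 40`, `D ≤ 800`).

## Known limitations

- The KNN wrapper is the only classifier exercised; the fitness callable is
  pluggable (`optimize(..., fitness_fn=...)`) but untested beyond KNN.
- With pure-error fitness, very easy datasets saturate at zero error and
  subset-size tie-breaking becomes the only selective pressure; on such
  data the returned subset is compact but not unique.
- Continuous-benchmark objectives (sphere, Rastrigin) are reachable through
  `fitness_fn` but are not part of the supported surface.
- Runtime is recorded per run but is hardware-dependent and never asserted.
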