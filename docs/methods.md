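# Methods

## The selection model

`gafs` treats feature selection as the maximization of a size-penalized
classification performance over binary inclusion vectors. For a dataset
with n candidate features, a chromosome θ ∈ {0,1}ⁿ encodes a subset, and

    fitness(θ) = Performance(θ) − α · |θ| / n,

where |θ| is the number of selected features and α (default 0.15) trades
performance against compactness. `Performance` is the mean metric over a
stratified k-fold cross-validation (k = 5) of the data visible to the
search; the fold assignment is a pure function of the master seed, so
fitness is a deterministic function of the chromosome. When the search
runs inside a candidate subset produced by a filter phase, n is the
chromosome length, i.e. the number of candidates — the penalty is
relative to the space actually searched.

Implications of the penalty worth keeping in mind when reading results:
a feature survives only if its marginal metric contribution exceeds α/n.
With few candidates (small n) the per-feature price is steep — on a
3-candidate space α/n = 0.05, enough to discard a genuinely informative
but partially redundant feature. This is intended behaviour of the
objective, not a search failure.

## Search strategy

Single population of r = 100 chromosomes. The initial population sets
every gene to 0 or 1 with equal probability, guarantees one all-ones
member (the all-features solution is always examined), and repairs
all-zero members by setting one random bit, since an empty subset has no
defined performance.

Per generation: r offspring are bred by binary-tournament selection
(two uniform draws per parent, the fitter wins; fitness ties break
toward the smaller chromosome, then the earlier member), two-point
crossover with probability 0.8 (two cut positions drawn uniformly from
the n+1 gaps, the enclosed segment swapped), and independent per-bit
mutation with probability 0.01 (all-zero offspring repaired). Parents
and offspring then compete and the best r survive.

This "best" replacement is the package's answer to a genuinely open
design point. It is the default population-replacement strategy of
classic master/slave GA libraries, it subsumes elitism (the incumbent
best can never be lost, so the best fitness is monotone
non-decreasing — the property the stopping rule presumes), and on noisy
fitness surfaces it prunes marginally harmful features considerably
faster than generational replacement with single-member elitism, whose
weak per-generation selection differential struggles against effects of
order α/n.

Stopping: after 100 generations, or as soon as the best fitness value is
unchanged for 50 consecutive generations (steady state). Both limits are
configuration-exposed.

Parallelism: fitness evaluations are pure functions of (chromosome,
data, fold split) and may be dispatched to a thread pool
(`worker_count`); results are reassembled in submission order and the
random stream is consumed only by the master loop, so any worker count
yields bit-identical runs. Evaluations are cached by chromosome bits;
for the naive Bayes classifier the evaluator precomputes per-fold,
per-feature, per-class log-density tables once, reducing a mask
evaluation to a masked sum plus argmax — numerically identical to the
plain path (asserted by tests) and the reason desk-scale searches take
seconds.

## Classifiers

*Naive Bayes* (in-house): Gaussian class-conditional density per
feature; class priors are empirical frequencies; per-class variances are
floored at 1e-9 · (global feature variance + 1) so constant features
degrade to flat densities instead of infinities. Prediction is the
argmax of log prior plus summed log densities, ties resolved toward the
lexicographically first class symbol.

*k-nearest-neighbours* (in-house): Euclidean distance over the selected
features, majority vote among the k (default 5) nearest training
points. Features are standardized with training-set mean and standard
deviation before distances (disable with `standardize=False`); distance
ties break toward the lower training index and vote ties toward the
lexicographically first class, making predictions exactly reproducible.
k and scaling are deliberate conventions — neither is dictated by the
problem — and are configuration-exposed.

*Combination*: the unweighted mean of the two classifiers' metric
values; the minimal aggregate that biases the search toward neither
model.

## Metrics and stability

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), GMean
√(sens·spec), F1 = 2·PPV·sens/(PPV+sens), accuracy, and Matthews
correlation. Indeterminate 0/0 forms return 0 (conservative); GMean is 0
whenever either factor is. Binary tasks take the lexicographically last
class symbol as positive unless configured; multiclass tasks are scored
one-vs-rest per class and macro-averaged (the unweighted mean treats
rare classes on par with common ones — deliberate for the imbalanced
tasks GMean is intended for).

Selection stability between two subsets of sizes k_i, k_j with c common
features out of n is the chance-corrected overlap
(c − k_i·k_j/n) / (min(k_i,k_j) − max(0, k_i+k_j−n)), range (−1, 1],
expectation 0 for uniformly random subsets (the numerator subtracts the
hypergeometric mean of c). It is undefined — and raised as an error —
when both subsets are the full feature set; the nested-CV harness
reports NaN in that case rather than failing, since full-set selections
carry no overlap information. Across k folds the statistic is averaged
over all k(k−1)/2 unordered pairs.

## Filters

Mutual information and conditional mutual information are plug-in
(maximum-likelihood) estimates on discrete codes, log base 2. Continuous
features are discretized into equal-frequency bins (default 10); bin
occupancies differ by at most one except under ties, which always share
a bin, so the coding is invariant to sample order. Integer-coded
features with at most `n_bins` distinct values are passed through
(recoded 0..k−1), keeping discrete fixtures exactly checkable against
closed-form values. The plug-in estimator is positively biased at small
n — roughly (|X|−1)(|Y|−1)/(2 N ln 2) bits — which matters when
comparing near-zero relevances; tests budget for it explicitly.

Greedy forward ranking scores a candidate X_k against the selected set S
as:

- mRMR: I(X_k;Y) − (1/|S|) Σ_{j∈S} I(X_k;X_j)
- JMI: Σ_{j∈S} I(X_k,X_j;Y)
- CMIM: min_{j∈S} I(X_k;Y|X_j)
- ICAP: I(X_k;Y) − Σ_{j∈S} max(0, I(X_k;X_j) − I(X_k;X_j|Y))

The first pick always maximizes I(X_k;Y); ties break toward the lowest
feature index. The correlation baseline ranks by |Pearson r| against a
0/1 class encoding (point-biserial), taking the maximum over one-vs-rest
encodings for multiclass; zero-variance features score 0. The hybrid
pipeline keeps the top ceil(fraction·n) ranked features (fraction 0.10
by default, at least one feature) and hands them to the GA as the
candidate space. Only the needed ranking prefix is computed — the greedy
order is prefix-consistent, so this is exact.

## Nested cross-validation

The outer k folds (default 5, stratified: per-class fold occupancies
differ by at most one) estimate generalization of the *whole* procedure.
Within each outer fold, selection runs on the outer-training rows only;
the wrapper's internal Performance signal is an inner k-fold (default 5)
cross-validation of those same rows. The reported per-fold metrics come
from refitting the classifier on the full outer-training rows with the
selected mask and scoring the untouched outer test fold — the refit
makes the reported number a property of the selected subset rather than
of the inner folds. Per-fold selection seeds derive deterministically
from the master seed and fold index. An optional audit trail records the
exact sample indices visible to selection per fold; the test suite
asserts the outer test rows never appear there.

The comparison utilities implement the usual tournament bookkeeping:
within each (dataset, metric) cell methods are ranked 1..m by value, tied
methods share the mean of their ranks (keeping per-cell point totals
constant), and points are summed across cells, smallest total first.

## Synthetic data

`make_informative_dataset` emulates the structure of classic hypercube
benchmarks: each informative feature carries a class-mean shift of
magnitude `class_sep` (default 1.0) with a random sign, plus unit
Gaussian noise, so every informative feature holds the same marginal
signal (per-feature d′ = class_sep); redundant features are scaled noisy
copies (scale uniform in ±[0.5, 2], noise sd 0.1) of a random
informative source; noise features are label-independent standard
normals; labels are exactly balanced, then flipped with `flip_prob`
(default 0 — label noise is opt-in). Column order is shuffled and
recorded in a `GroundTruth` (informative indices, redundant→source map,
noise indices). The default `class_sep` = 1.0 puts single-feature GMean
near 0.69 and ten-feature GMean near 0.94: strong enough to rank above
noise, weak enough that the wrapper must combine features — the regime
wrapper selection exists for. `make_xor_dataset` plants two continuous
features whose sign product determines the label (each marginally
independent of it): the canonical case univariate rankings cannot see.
`make_binary_dataset` emits 0/1 features through a binary symmetric
channel for exact-MI oracle tests.

What the generators do *not* emulate: correlated noise blocks,
batch effects, heavy-tailed measurement error, missing values, and
class-dependent covariances. Passing tests therefore demonstrate the
machinery's correctness and its behaviour in a controlled signal/noise
regime, not performance on any particular real assay.

## Numerical and scale choices

Tables are tab-delimited, last column = class label; a first row whose
non-label fields are not all numeric is treated as a header. Missing
values are rejected, as are single-class tables. Written floats use
`repr`, which round-trips doubles exactly.

Problem sizes in the test suite are chosen for a laptop-class single
core: the heaviest check runs the full default GA (population 100, 100
generations) ten times on a 500-sample, 100-feature table, which the
cached NBC fitness path completes in a few seconds per run. Stability
simulations use 1000–2000 random pairs; estimator-oracle sweeps use ≤ 64
samples and ≤ 4 symbols where the brute-force reference is exact.

## Known limitations

- The GA gives no optimality guarantee; on the noisy inner-CV fitness
  surface it retains a few noise features whose spurious inner-fold gain
  exceeds α/n (visible in the README example).
- The plug-in MI estimator with 10 equal-frequency bins is biased for
  continuous features at small n; kernel/KSG estimators are out of
  scope.
- Multiclass metrics are macro-averaged only.
- Filter rankings are O(n_keep · n) pairwise MI evaluations; for tables
  with tens of thousands of features the filter phase dominates runtime.
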