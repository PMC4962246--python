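# Methods

## The model

The screen treats ER-binding prediction as binary classification over a
numeric descriptor matrix (rows = compounds, columns = descriptors, all
dimensionless). Two training corpora of different size and binder
prevalence stand behind the two models; since the screen only consumes
their fitted forests' probabilities, the package accepts any externally
computed descriptor table (e.g. Mold2's 777 descriptors) and never
computes descriptors itself.

### Decision Forest

A Decision Forest is grown as follows:

1. Fit a CART classification tree on the full training set using every
   available descriptor.
2. Remove from the pool **every** descriptor used in any split of that
   tree.
3. Repeat with the reduced pool; keep the candidate tree only if the
   forest's training misclassification count (under probability
   averaging) strictly decreases; stop at the first non-improving
   candidate, at zero training error, when the pool is exhausted, or at
   `max_trees`.
4. Predict by averaging, over member trees, the binder fraction
   `n_active / n_total` of the terminal node the compound falls into;
   call binder iff the mean exceeds 0.5.

The first tree is always kept: a tree is never worse on its own training
set than the empty model, so the strict-improvement rule is well defined
from the second candidate onward. This operationalization of "training
improvement" (misclassification count of the averaged forest) is a design
choice — the construction is also compatible with other statistics, and
the original description does not pin one down. No pruning is applied.

Tree induction details that affect reproducibility:

- Split criterion: Gini impurity (pluggable identifier; only `gini`
  implemented). Candidate thresholds are midpoints between consecutive
  distinct sorted values of a descriptor.
- Tie-break: among splits of equal impurity, the lowest descriptor column
  index wins, then the lowest threshold. Split scores are compared in the
  rational form `aL(nL−aL)/nL + aR(nR−aR)/nR` whose integer products are
  exact in float64 at these problem sizes, so ties are detected exactly
  and fits are bit-reproducible across runs.
- Growth stops at `max_depth` (default 10), at pure nodes, below
  `min_split_size` (default 4, ≥ 2·`min_leaf_size`), when both children
  cannot reach `min_leaf_size` (default 2), or when no split strictly
  reduces impurity. Defaults are sized so training sets of a few hundred
  compounds yield non-trivial trees.
- Terminal probabilities are raw fractions; Laplace smoothing is
  available behind `TreeParams(smoothing=True)` but off by default.
- No bootstrapping and no feature subsampling — determinism comes from
  the data, not from a seed, though a seed field is carried for API
  stability.

### Consensus and confidence

The consensus probability is the unweighted mean of the model
probabilities (the API accepts k ≥ 2 models; the screen uses exactly
two). The boundary p = 0.5 is a non-binder. Confidence rescales distance
from the boundary to [0, 1]: `|p − 0.5| / 0.5`. Reports render
probabilities and confidence to 3 decimals (round half to even); full
precision lives in the JSON sidecar. Of the 29 packaged published rows,
six print a confidence that differs by ~0.001 from the value implied by
their rounded probabilities — display rounding of unrounded internal
values, not a different formula — and the published abstract's "fifteen
binders" disagrees with the table's own arithmetic of 14; the package
follows the arithmetic.

### Affinity conversion

`logRBA = −7.719 − 0.086·ΔG`. Free energies are taken to be kcal/mol
with the MM-GBSA sign convention (more negative = stronger binding);
the source regression does not state units explicitly, so this is
recorded as an assumption. The coefficients are package defaults,
overridable per call and via the CLI. Compounds whose docking failed are
simply absent from the energy map and are reported with
`logrba_status = "failed"`.

## Validation machinery

- Metrics: accuracy, sensitivity, specificity, MCC and balanced accuracy
  evaluated exactly as the standard confusion-table formulas; MCC with a
  zero denominator factor is defined as 0; metrics require both classes
  present in the truth vector.
- Cross-validation: per repetition, a fresh plain-random partition into k
  near-equal folds (stratified available via flag); a forest is fitted on
  k−1 folds and predicts the held-out fold; the k held-out prediction
  sets are **pooled** into one confusion table per repetition, weighting
  compounds equally and staying well defined when a fold lacks a class.
  Per-repetition metrics are then averaged (population std). A partition
  that strands a training split with one class is redrawn with an offset
  seed (up to 10 times, logged). Default 200 repetitions; tests use
  10–20.

## Synthetic data

The generator emulates the statistical skeleton the pipeline assumes:
Gaussian descriptors, of which `n_informative` are shifted between
classes by `effect_size · noise_sd`, plus exact-duplicate and constant
columns to exercise preprocessing. Tree splits depend only on value order
within a column, so Gaussian marginals exercise the classifier as well as
any monotone transform; an `integer_like` flag converts part of the noise
block to Poisson counts to mimic mixed descriptor types. Two presets are
fixed: **strong** (232 compounds / 131 binders / 777 descriptors, 10
informative, effect size 2.0 — the size and prevalence of the smaller
training corpus, with signal strong enough to be learnable) and **null**
(100 compounds, balanced, no signal) for chance-level calibration.

What the generator does **not** emulate: real descriptor correlation
structure, scaffold clustering, activity cliffs, and class-dependent
noise. Passing tests therefore demonstrate that the machinery is correct
and calibrated, not that any particular accuracy carries over to real
chemistry; the published cross-validation and external-validation numbers
depend on the original curated training data, which are not
redistributable, and are deliberately not reproduction targets. The
substitute checks fix the problem sizes stated above (strong preset CV at
k = 5 with 20 repetitions; 50 small 60×25 datasets for the structural
invariants), chosen to exercise the full pipeline at desk scale.

## Degenerate inputs and numerical choices

- Preprocessing: "duplicate" means bit-identical value vectors after
  parsing; near-duplicates and high correlation are out of scope.
  Constant columns are removed under their own rule even when two
  constants share a value. First occurrence wins. Idempotent by
  construction.
- Missing descriptor values are an error, never imputed.
- A single-class training set yields a degenerate one-leaf forest rather
  than an error (probability 0 or 1 for everything).
- Midpoint thresholds guard against underflow: if the midpoint of two
  adjacent distinct values rounds down to the lower value, the upper
  value is used as the threshold so the partition stays non-trivial.
- Serialized forests are JSON; floats survive the round trip bit-exactly,
  so a loaded model reproduces predictions identically.

## Known limitations

- The DF stopping statistic and tree hyperparameters are package choices;
  the original algorithm's exact settings are not published, so fitted
  forests here are *a* faithful Decision Forest, not a byte-level
  re-creation of the original models.
- Consensus is an unweighted mean; no probability calibration or model
  weighting is attempted.
- The affinity conversion is a fixed affine map; its regression is not
  refit (its training data are external) and cannot be verified
  end-to-end against the published per-compound logRBA values because the
  underlying free energies are not published.
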