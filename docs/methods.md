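# Methods

## Problem and model

Given an `n × d` numeric table with binary labels (positive = "normal"),
wrapper feature selection searches the lattice of the `2^d − 1` nonempty
feature subsets for the one on which a classifier generalizes best. Each
subset `S` is scored by training the classifier on the training partition
restricted to `S` and measuring accuracy on held-out data:
`F(S) = (1/n_val) Σ I(ŷ_i = y_i)`. The minimized objective is the composite

    f(S) = α (1 − F(S)) + (1 − α) |S|/d.

`α` weights accuracy against subset size; the default `α = 0.99` is the
convention in the wrapper-selection literature — the size term then only
breaks near-ties in accuracy. At `α = 1` the objective is pure error; at
`α = 0` it is pure parsimony.

Holdout accuracy on a small validation set is coarse (a 62-sample holdout
can only produce multiples of 1/62), so `evaluate_config` also supports
averaging over stratified k-fold cross-validation of the training part
(default 10 folds for tuning, folds=1 meaning plain holdout). CV averaging
is what produces non-grid accuracy values in fine-grained comparisons.

## Breadth-first searches

Both searches share one engine: evaluate the root, then expand levels FIFO;
successors are generated in a fixed deterministic order, marked visited at
enqueue time (no state is evaluated twice), and the best-ever record is kept.

* **Feature selection (BBFS).** Root = all-ones mask ("begin with every
  feature under consideration"). Successors are all feasible single-bit
  flips — removals *and* re-additions, so the search can recover a feature
  dropped at an earlier level; a `removal_only` flag restricts to the
  strictly shrinking variant. On `d ≤ 15` the default beam is unbounded and
  an unbounded budget visits the entire lattice, making the search exactly
  equivalent to exhaustive enumeration (this is tested).
* **Hyperparameter tuning.** The grid graph connects configurations
  differing by one step along one axis. Root = scikit-learn defaults, which
  yields the root-inclusion guarantee: the tuned configuration is never
  worse than the default on the tuning objective, on every seed, by
  construction. The default random-forest grid is
  `n_estimators {50,100,200} × max_depth {3,5,10,∞} × min_samples_leaf
  {1,2,4} × bootstrap {true,false}` (72 points).

Halting combines four mechanisms: an evaluation budget (`max_iterations`,
root included; the conventional reference setting is 100), a level cap, an
optional beam (`beam_width` best states of each level survive; stable sort,
so fitness ties preserve evaluation order), and patience (halt after k
levels without improving the best fitness). Fitness ties are always broken
in favour of the earliest-evaluated state, which makes the otherwise
order-unstable BFS fully deterministic. The legacy configuration fields
`graph_vertices = 5` / `graph_edges = 6` are provenance metadata carried in
run configs; they do not drive the search (no consistent interpretation
exists on a subset lattice of 63 vertices).

## Swarm baselines

The binary comparisons use the canonical update rules — Kennedy–Eberhart
PSO, and the Mirjalili grey-wolf and whale algorithms — since no
alternative formulation is specified for the binary variants:

* **BPSO**: velocity `v ← w v + c₁ r₁ (pbest − x) + c₂ r₂ (gbest − x)`,
  inertia scheduled linearly from 0.8 down to 0.5, `c₁ = c₂ = 2.0` by
  default (`SwarmConfig.reference()` exposes the reference presets,
  including acceleration `[5, 5]` and the per-algorithm populations PSO 50,
  WOA 200, GWO 20, 100 iterations). Velocities are clamped at ±6 so the
  sigmoid stays off its saturation plateaus. Bits are drawn
  `bit = 1 iff u < σ(v)` with `σ(v) = 1/(1+e^{−v})`.
* **BGWO / BWOA**: continuous positions updated from binary leaders
  (`a` decreasing linearly 2 → 0; GWO averages the α/β/δ pulls, WOA takes
  the encircle/explore/spiral branches at p = 0.5), clipped to `[0,1]`,
  then binarized through a sharpened centred sigmoid `σ(10 (x − 0.5))`.
  The sharpening is needed because positions live in `[0,1]`: the plain
  sigmoid of such a position is confined to `[0.5, 0.73]` and cannot
  commit to a bit. With the gain of 10 a converged position maps to a bit
  probability of ≈ 0.993.

All-zero masks are infeasible and are repaired by setting one uniformly
chosen bit. One `numpy` generator per run, seeded from the config, drives
initialization, binarization and repair — traces are bitwise reproducible.
Continuous tuning variants move in the box spanned by the grid axes'
numeric encodings (unbounded depth = axis max + 1, booleans = 1/0) and
snap to the nearest grid value before each evaluation.

## Metrics and statistics

From TP/TN/FP/FN: accuracy, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F-score, and an "AUC" defined as the
balanced accuracy `(sensitivity + specificity)/2`. That definition is kept
for table reproduction because it is the convention this package's report
layout follows; it differs from the ranking ROC-AUC (which can reach
100 % while accuracy does not), so `ranking_auc` computes the score-based
ROC variant and the tuned-model tables report both. Zero-denominator
metrics are defined as 0 with a warning rather than NaN, keeping summary
tables total. Fit wall-times are measured and written to the run log only:
they are hardware-dependent, and keeping them out of the CSV tables is what
makes the tables bytewise reproducible.

Cross-run summaries report, over each optimizer's per-run best fitnesses:
the average error `mean(f_i − f*)` against a reference optimum (supplied,
or in auto mode the best fitness observed across all compared traces, which
makes every error ≥ 0), the mean/best/SD of fitness (sample SD, n−1), and
the mean selected-size ratio of the best masks.

One-way ANOVA is computed from the classical sums of squares with the p
value from the F distribution; the all-groups-identical case is surfaced
as a `residual_zero` flag instead of a division error. The experiment
runner's ANOVA treats optimizers as treatments and per-seed best fitness
(or per-seed tuned validation accuracy) as observations — the treatment
structure behind the reference report is unstated, and this is the
package's documented interpretation.

## Preprocessing

* **KNN imputation** (default k = 10) fills a missing cell with the mean of
  the k nearest rows by Euclidean distance over mutually observed features,
  rescaled by `sqrt(d / #shared)`; rows missing the target feature are
  ineligible donors. This is exactly scikit-learn's `KNNImputer` contract,
  so that estimator implements the step. Mean substitution and
  drop-missing (which also removes exact duplicate rows) are provided as
  alternatives.
* **Standardization** uses the training part's mean and *population* SD
  (the scikit-learn scaler convention); constant columns use σ := 1 so
  their z-scores are 0. Held-out data is always transformed with the
  training parameters.
* **Splitting** is stratified (default 80/20 — the reference protocol
  states a two-part split without a ratio; 80/20 is the field's default)
  with a mandatory seed.

With preprocessing disabled, raw values including missing cells go straight
to the models; tree ensembles handle NaN natively, and estimators that
cannot train score fitness 0 with a warning so searches remain total.

## Synthetic data

The generator emulates the reference cohort's *shape*: labels
Bernoulli(0.677419), features independent Gaussians with the published
per-feature means/SDs for `d = 6` (standard normal otherwise), planted
informative features whose class-conditional means are separated by
`effect_size` SDs, and MCAR cell masking that never blanks a whole row or
column. An optional log-normal mode exists for the heavily right-skewed
spondylolisthesis column (population min −11, max 418), default off.

What it deliberately does **not** model: the real measurements' strong
correlation structure (pelvic incidence is by definition close to pelvic
tilt + sacral slope), skewness (outside the optional log-normal mode),
label noise, and informative missingness. Passing tests on this generator
therefore demonstrate the correctness of the search/metric machinery and
recoverability of planted signal under known conditions — not clinical
performance on the real cohort, whose published headline accuracies depend
on an external dataset and an unstated split/CV protocol and are treated
as non-reproducible references throughout.

## Problem sizes and numerical choices

* Planted-feature recovery is checked at the reference scale (n = 310,
  d = 10, 3 informative features at 1.5 SD, α = 0.99, 5-fold CV) with a
  Gaussian naive-Bayes wrapper: for independent Gaussian features with
  class-mean shifts, NB is the correctly specified classifier, and its
  speed lets the search cover the full 1023-mask lattice on every seed.
* Oracle-equivalence checks run on lookup-table landscapes (d ≤ 6, 72-point
  grids), where exhaustive enumeration is the independent oracle.
* Experiment-runner checks use reduced budgets (order 10–100 evaluations,
  n of order 100–300) — the guarantees they verify (root inclusion,
  determinism, budget accounting) are size-independent.
* Equal-budget comparisons cap every optimizer at the same evaluation
  count; the counts are exactly equal as long as no search exhausts its
  space first (BBFS on d = 6 has only 63 feasible states).
* Master seeds split into named component streams via SHA-256 of
  `(master, component, run)`, truncated below 2^31 — adding an optimizer
  to a config never perturbs the other components' draws.
* In the tuned-model tables, all tuners share one refit seed, so rows
  differ only through the configurations the tuners found.

## Known limitations

* BBFS cost grows combinatorially; beyond d ≈ 15 a beam and budget are
  required, and the exhaustive-equivalence guarantee no longer applies.
* Single-bit-flip search cannot jump between distant subsets; interacting
  feature pairs whose joint effect is invisible marginally can be missed
  (the classic XOR case).
* The balanced-accuracy "AUC" and the ranking ROC-AUC can disagree
  substantially; both are reported, and users should pick the one matching
  their comparison target.
* Only binary labels and numeric features are supported, by design.
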