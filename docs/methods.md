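# Methods

## Model

`errorcascade` implements a three-stage stacked ensemble for binary
classification of numeric tabular records in which the *training-set
composition* of later stages is decided by the per-instance errors of
earlier stages, rather than by meta-features or learned gating.

Let the training partition be split into a core set (fraction
`stage1_fraction`, default 0.6) and a routing set. Stage I fits Gaussian
naive Bayes, a k-nearest-neighbour vote and an information-gain decision
tree on the core set. On the routing set, define per-learner correctness
indicators; pool A is the set of routing instances where NB and k-NN are
both correct, pool B where k-NN and the tree are both correct, and pool F
the remainder. Pools A and B may overlap; F is disjoint from both, so
(A ∪ B) ∪ F covers the routing set exactly — an invariant asserted on
every fit. Stage II fits a random forest on pool A and an ordered rule
list (RIPPER-style) on pool B. The stage-III training set is the union of
the routing instances at least one stage-II learner classifies correctly
(`stage2_rule="union"`; intersection is available) with pool F, each with
its original label; a linear-kernel SVM fit on this set is the entire
inference path. The intuition: stage II distils the regions the simple
learners already handle, while pool F injects exactly the hard instances,
so the final margin learner sees a training set re-weighted toward both
the reliable core and the failure modes.

Several aspects of this protocol were genuinely open and are package
decisions:

- **No leakage by construction.** Routing correctness is measured on a
  held-in subset of the training partition, never on evaluation data, and
  LDA/SMOTE are fit on training data only. A protocol that routed on the
  evaluation split would contaminate every reported metric.
- **Pool B pairing.** The second pairwise-true pool uses k-NN with the
  decision tree — the remaining stage-I pair. The pairing is a constructor
  parameter (`pair_a`, `pair_b`).
- **Stage-II truth = union.** An instance reaches stage III if *either*
  stage-II learner gets it right; union maximises the data reaching the
  final learner. Intersection is one flag away.
- **Inference = stage-III SVM only.** Stages I–II shape the final
  training set; they are not consulted at prediction time. The cascade
  therefore exposes `decision_function` (the SVM margin) for ranking
  metrics, but no probability outputs.
- **Degenerate pools.** An empty pool A or B skips that stage-II learner
  with a warning; an empty or single-class stage-III set is a hard error.

## Representation: scatter-matrix LDA

All stages share one representation. By default a linear discriminant
projection is computed from first principles: per-class means, the
within-class scatter S_W = Σ_c Σ_{i∈c}(x_i−μ_c)(x_i−μ_c)ᵀ and
between-class scatter S_B = Σ_c n_c(μ_c−μ)(μ_c−μ)ᵀ, the eigenpairs of
S_W⁻¹S_B sorted by descending eigenvalue, and the projection Z = Xw
through the top-m unit-norm eigenvectors. For C classes S_B has rank at
most C−1, so m defaults to C−1 — a single axis for the binary task, which
deliberately turns every downstream learner into a thresholding problem
on the Fisher axis. `use_lda=False` runs the cascade on raw features.
Numerical choices: eigenvector sign is fixed by making the first non-zero
coordinate positive (the sign is otherwise arbitrary); a numerically
singular S_W (possible in small folds) falls back to the Moore–Penrose
pseudo-inverse at relative tolerance 1e-10 with a warning; eigenvalues of
the non-symmetric product are real up to round-off and the real part is
taken.

## Base learners

Gaussian naive Bayes (posterior ∝ likelihood × prior, computed in log
space and renormalised; per-class per-feature variances floored at 1e-9
times the largest feature variance), the k-NN vote (unweighted Euclidean,
k ≤ 20, default 5; vote ties broken by smaller summed distance then
smaller label) and the information-gain statistic (entropy in bits) are
implemented natively. The decision tree (entropy criterion), random
forest (default 100 trees, majority vote) and linear SVM (default C = 1)
are scikit-learn estimators behind the same fit/predict/score contract.
The ordered rule learner is a native IREP-style implementation: each
rule is grown on 2/3 of the remaining data by greedily adding numeric
threshold conditions maximising FOIL information gain until no negatives
are covered, pruned on the other 1/3 to the condition prefix maximising
(p−n)/(p+n), and induction stops when a pruned rule is below 50 %
precision on the pruning set; candidate thresholds are midpoints of
sorted unique values, subsampled to 24 per feature for tractability. Rule
scores are Laplace-smoothed training precisions, which gives the rule
list a usable ranking score for AUC. None of the learner hyperparameters
above has an externally mandated value; the defaults are recorded here
and in `LearnerSpec` and are all overridable.

Positive-class scores for ranking are `predict_proba[:, 1]` where
available and the signed decision margin for the SVM.

## Data handling

Cleaning treats a cell equal to exactly 0.0 in Glucose, BloodPressure or
BMI as a missing-value code (no epsilon: the zeros are codes, not small
measurements) and drops the affected rows; the profiled column set is a
parameter. The operation is idempotent and reports per-column zero counts
plus the dropped row indices.

SMOTE is implemented natively: each synthetic minority record is
x_i + u·(x_nn − x_i) with u ~ U(0,1) and x_nn drawn among the k = 5
nearest minority neighbours of a uniformly chosen minority record;
originals are preserved verbatim and the draw is deterministic given the
seed. SMOTE is only ever applied to training data — the stage-I core
subset inside the cascade, or the training folds inside CV (per-fold by
default; a global pre-balancing flag would leak synthetic points into
test folds and is intentionally not the default).

## Synthetic generator and what it does (not) show

The generator draws labels Bernoulli(class_prior) and features from
class-conditional Gaussians with a shared covariance, then zero-inflates
selected columns independently of the label. Defaults emulate the
reference diabetes dataset: n = 768, positive prior 268/768 ≈ 0.349,
feature locations and spreads on clinically plausible scales (glucose
~110 ± 25 mg/dL, BMI ~31 ± 6.5 kg/m², …), a shift direction raised in
glucose/BMI/age/pregnancies scaled to Mahalanobis separation Δ = 2, and
3 % zero inflation in the three cleaning columns. Δ = 2 was chosen
because it puts the Bayes accuracy ceiling at Φ(1) ≈ 0.841, a realistic
difficulty for this kind of clinical tabular problem.

Shared covariance makes the Bayes rule linear, with closed-form error
π₀Φ(−Δ/2 − c/Δ) + π₁Φ(−Δ/2 + c/Δ), c = log(π₀/π₁) — equal priors give
Φ(−Δ/2) — and optimal direction cov⁻¹(μ₁−μ₀). This is what makes the
recovery tests sharp: LDA should align with the optimal axis and
well-specified learners should approach the Bayes bound. It is also the
generator's main idealisation: real clinical data have skewed, partly
discrete marginals, class-dependent covariance and informative
missingness. Passing the recovery tests therefore demonstrates
correctness of the machinery, not expected real-data performance; the
zero-inflation mechanism exercises the cleaning path but is
label-independent by design, unlike real missingness.

## Evaluation

Metrics are reported for the positive class (outcome 1): recall
TP/(TP+FN), precision TP/(TP+FP), their harmonic mean F, and AUC via the
Mann-Whitney rank statistic with ties at ½ (identical to trapezoidal ROC
integration). Zero-denominator ratios return 0 with a warning instead of
raising, so CV loops survive degenerate folds. The CV harness runs
stratified k-fold (default k = 10) for `repeats` rounds (default 3) with
fold seeds seed, seed+1, …; every model factory is evaluated on identical
folds, giving k·repeats records per model, and the whole result is
bitwise reproducible from the master seed.

## Problem sizes

The test-suite and acceptance computations use the generator at the
scales the analyses call for: 768 records for cleaning, 2000/2000
train/test at Δ = 2 for Bayes-bound recovery, and 724 records (the
cleaned-dataset scale) for the seven-model repeated 10 × 3 CV. These
sizes give sampling errors comfortably inside the stated tolerances
(±3 accuracy points against the Bayes bound; < 5° LDA angle) while the
full suite runs in well under a minute on one CPU.

## Known limitations

- Exactly three stages with fixed learner roles; routing policy is
  configurable only through the pair definitions and the union/
  intersection rule.
- No probability calibration on the cascade output.
- The rule learner implements IREP-style induction, not the full
  post-pruning/optimisation passes of later RIPPER variants; its contract
  (ordered rules, grow/prune, reduced-error pruning, deterministic under
  seed) is what the ensemble needs.
- Binary outcomes only; the LDA path intentionally collapses binary
  problems to one axis, which changes the behaviour of neighbourhood and
  tree learners relative to raw features — both representations are
  supported, LDA being the default.
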