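# Methods

This note documents the models and procedures implemented in `ppcml`, the
assumptions behind the synthetic cohort generator, the numerical and design
choices made where the problem was genuinely open, and what the test suite
does and does not demonstrate.

## 1. Synthetic cohort generator (`ppcml.cohort`)

The generator emulates a single-center cohort of 286 NSCLC patients
undergoing video-assisted thoracoscopic resection, with a binary
postoperative pulmonary complication (PPC) endpoint at 31.12% prevalence.

**Marginals.** Twelve continuous variables (age, BMI, FEV1 fraction, WBC,
neutrophil %, platelets, CRP, hemoglobin, albumin, glucose, blood loss,
operative time) are drawn from truncated normal distributions (mean ± 4 sd)
matching the published training-cohort means and SDs; truncation prevents
impossible values such as negative blood loss. Eight categorical variables
(sex, smoking, hypertension, diabetes, coronary artery disease, surgical
approach, pathological type, pathological stage) are independent
multinomials at the published proportions. All variables are mutually
independent: the generator's purpose is a controlled, fully-known
data-generating process for testing the downstream stack, not clinical
realism. Real cohorts have correlated predictors (e.g. smoking with FEV1);
nothing here exercises that structure, so passing tests say nothing about
behavior under collinearity.

**Outcome model.** PPC is Bernoulli with logit

```
logit P(ppc=1) = β₀ + Σ_j β_j z_j + γ₁ z_age z_wbc + γ₂ c_approach z_crp
```

where `z` are z-scored continuous predictors (published means/sds, not
sample moments), `c_approach` is the centered lobectomy indicator
(±0.5), the six main effects cover WBC, BMI, approach, age, blood loss and
CRP, and the two interaction terms plant the age×WBC and approach×CRP
synergies that the interpretability stack is expected to recover. The
intercept is not free: `calibrate_intercept` solves for β₀ by a bracketed
1-D root find (Brent, on [−50, 50]; the mean logistic probability is
strictly increasing in β₀) so the cohort-mean predicted probability equals
the target prevalence to 1e-6.

**Default effect sizes.** The defaults (WBC 1.5, BMI 1.2, approach 2.1,
age 1.05, blood loss 0.9, CRP 0.8; interactions 0.75 and 1.2, per-SD
log-odds) were calibrated once so that a tuned gradient-boosted model on an
n = 286 cohort reaches test ROC-AUC in the 0.85–0.95 band — the difficulty
regime the package targets. Under these defaults the Bayes-optimal AUC
(scoring with the true linear predictor) is ≈ 0.92 at large n. The scale is
deliberately strong; individual high-risk patients can receive probabilities
near 1.

**Missing data.** An optional fraction of operative-time values is set
missing; the pipeline mean-imputes the column before model fitting,
mirroring the routine handling of incomplete surgical records.

## 2. Baseline statistics (`ppcml.stats`)

Pearson chi-square on contingency tables uses `Σ (O−E)²/E` with no
continuity correction — the published baseline-table statistics match the
uncorrected form exactly. Two-sample comparisons use the pooled-variance
Student t by default (Welch optional). The stratified train/test split
fixes the global train size at round-half-up of `ratio·n` and allocates it
across outcome strata by the largest-remainder rule, which reproduces the
229/57 partition of a 286-row cohort at ratio 0.8 and keeps each part's
prevalence within one count of proportional (exact proportionality is not
always integer-feasible). Assignment within a stratum is a seeded shuffle.

## 3. Benchmark suite (`ppcml.benchmarks`)

Twelve functions on `[−100, 100]^d`, categories 3/5/4
(unimodal/multimodal/composite). Basic functions: Zakharov, Rosenbrock,
high-conditioned elliptic; Rastrigin, Levy, Schaffer F7,
Griewank–Rosenbrock, Schwefel — each shifted (uniform within the central
80% of the box) and rotated (QR of a seeded Gaussian matrix, sign-fixed for
uniqueness), with per-function input scaling so the classic landscape fits
the box. Composites combine 3–5 basic components with distinct
shifts/rotations through the standard distance-based weighting
`w_i ∝ exp(−d_i²/(2dσ_i²))/d_i` (normalized; a query exactly on a
component's shift receives that component alone), per-component value
scalings λ_i and biases 0, 100, 200, …; the first component carries zero
bias, so every function's global optimum value is exactly 0 at a known
point. The official competition data files are not used: this is a seeded,
structurally equivalent suite for *relative* optimizer comparisons, and
function numbers do not correspond to any official numbering.

## 4. Leech optimizer (`ppcml.optimizer`)

Minimization over a box; population `N ≥ 4`; objectives take an `(n, d)`
matrix and return `n` values, so a whole population costs one call.

One BSLO generation applies five strategies: (1) *directional exploration*
`x′ = x + r₁(best − x) + (2r₂−1)(x_a − x_b)` with random peers `a, b`;
(2) *directional exploitation* `x′ = best + s(1 − t/T)(2r−1)|best − x|`
with step scale `s` (default 1); (3) *directional switching*: each leech
explores with probability `(1 − t/T)^p` (default p = 1), else exploits;
(4) *non-directional search*: a fraction (default 10%) is relocated
uniformly at random; (5) *retracing*: a leech whose fitness has not
improved for 15 consecutive generations restarts from a fresh uniform
position. Candidates are clamped to the bounds; greedy replacement keeps a
move only if it does not worsen that leech (retraced leeches always move).
The global best is tracked separately, so the best-so-far trace is monotone
even across restarts. Ties in argmin break to the first index.

The exact update equations of the original leech algorithm are not
published alongside the strategy names; the forms above implement the
stated strategy roles with all constants exposed in `StrategyParams`.

IBSLO adds: (a) cubic chaotic-map initialization — one orbit of
`z ← ρ z (1 − z²)`, ρ = 2.595 (orbit strictly inside (0, 1); seeded start
drawn from (0.05, 0.95)), unrolled across all position genes; and
(b) dynamic opposition-based learning — with probability 0.3 per
generation, every leech's opposite `a + b − x` against the current
population's per-dimension extent is evaluated and the best N of the 2N
union survive (elitist, hence never degrades the best). Opposition against
the population extent rather than the static bounds keeps opposites
informative as the swarm contracts; whether the original method applied
opposition every iteration or probabilistically is unreported, so the
probability is a configurable default.

## 5. AutoML engine (`ppcml.automl`)

**Encoding.** A unit-cube vector `(k | δ | λ)`: learner id
`k = 1 + ⌊4·raw₀⌋` (clamped; 1 = logistic regression, 2 = RBF-SVM,
3 = XGBoost, 4 = LightGBM), feature mask bits `δ_j = [raw_{1+j} > 0.5]`
(an all-zero mask is repaired by setting the largest gene's bit, keeping
the search space total), and hyperparameter genes mapped into the selected
model's ranges — log-scaled by exponent interpolation, integers rounded.
λ is sized to the largest per-model space; surplus genes are inactive for
smaller spaces. LightGBM/XGBoost ranges: learning rate [1e-5, 0.1] (log),
depth 3–12, subsample 0.6–1.0, L2 [1e-6, 1e-2] (log); tree count is fixed
(default 80, 60 in the scaled experiments), not searched. LR and SVM sit
behind a standardizer in a pipeline — the raw features span roughly 0.8 to
240 units, which would otherwise dominate the RBF kernel and the L2
penalty. SVM probabilities come from Platt-style sigmoid calibration.

**Fitness.** `f = w₁(t)·ACC_cv + w₂(t)·(1 − ‖δ‖₀/m) + w₃·exp(−T/T_max)`,
with stratified 10-fold cross-validated accuracy, maximized (negated for
the minimizing optimizer). `w₁` decays 1.0 → 0.6 and `w₂` grows 0 → 0.03
linearly over iterations; `w₃ = 0.05`. Two choices deserve justification:

* *Cost term.* `T` is a deterministic training-cost proxy (relative
  learner cost × a feature-count factor), not wall time: measured time
  would make the fitness irreproducible across calls, violating the
  determinism contract, while the proxy preserves the intent — cheaper
  configurations earn a small bonus.
* *Terminal sparsity weight.* The per-feature parsimony bonus is
  `w₂(T)/m / w₁(T)` in accuracy units (≈ 0.4 accuracy points at m = 13).
  It is deliberately placed *below* the resolution of repeated
  cross-validation, making sparsity a tie-breaker: a feature is pruned
  when it adds no measurable accuracy, never in exchange for measurable
  accuracy. Larger weights (e.g. a bonus of 3 accuracy points) were
  measured to systematically discard weakly informative predictors whose
  removal costs real test AUC.

**Search.** IBSLO over the `1 + m + 4`-dimensional cube. The initial
population is warm-started with four full-feature reference candidates
(one per learner at reference hyperparameters), so the pool always
contains the unpruned baseline configurations. Decoded candidates are
cached on their decoded identity; cached entries store the weight-free
terms (accuracy, sparsity, efficiency) and the schedule weights are
re-applied at the current iteration, keeping the dynamic weighting honest
while avoiding refits of revisited candidates.

**Winner selection.** Fitness values recorded at different iterations are
on different weight scales (an early accuracy-heavy value always dominates
a terminal parsimony-weighted one), so the final model is *not* the
optimizer's raw best-so-far: all evaluated candidates are re-scored at the
terminal weights, the top 8 are confirmed with repeated cross-validation
(5 fold seeds — the single-CV argmax over ~10² candidates is optimistically
biased by roughly two accuracy points), and the confirmed argmax is refit
on the full training table. Test rows never enter the search: the search
function only receives the training table.

## 6. Evaluation (`ppcml.metrics`)

Threshold metrics use predicted-positive iff `p ≥ τ` (default τ = 0.5, the
conventional reporting threshold); undefined ratios (zero denominators)
are reported as NaN rather than coerced to 0. ROC-AUC equals the
Mann–Whitney statistic with ties counted ½. PR-AUC is the step-curve
(average-precision) sum — trapezoidal interpolation between PR points is
optimistic and avoided. Decision curves report
`NB(p_t) = TP/N − FP/N · p_t/(1−p_t)` on a default grid 0.01–0.99 (step
0.01) against treat-all and treat-none; net benefit of the model is not
asserted to dominate in general — that is an empirical property of a
particular model on particular data.

## 7. Interpretability (`ppcml.explain`)

Attributions are on the margin (log-odds) scale for all learners, recorded
in the output metadata. Tree models use the exact tree-path Shapley values
computed natively by the boosting libraries; additivity
(base + row sum = margin) is exact up to float accumulation. LR/SVM use a
seeded permutation-sampling estimator against a background sample (default
first 100 rows): each permutation telescopes from the background mean
output to the explained sample's output, so per-sample additivity holds
identically regardless of the number of permutations (the *split* among
features, not their sum, is what sampling approximates). Importance is the
mean absolute attribution, ties broken by feature name. Interaction
strengths: XGBoost models use the native exact pairwise interaction
values (mean absolute over samples); other models fall back to a sampled
second-difference estimator `f(S∪{i,j}) − f(S∪{i}) − f(S∪{j}) + f(S)`
averaged over random coalitions and the background. The matrix is
symmetrized exactly; diagonals carry main-effect strengths.

## 8. Experiment sizes

The shipped experiments use scaled problem sizes chosen to keep the full
suite and the acceptance script comfortably reproducible on one CPU:
optimizer comparison at dimension 10, population 30, 200 iterations, 10
runs per variant; AutoML searches with population 10, 12 iterations, 60
trees, 10-fold CV on n = 229 training tables; interaction-detection at
n = 1000 (pairwise interaction recovery at n = 286 is underpowered);
coefficient recovery at n = 5000 over 20 replicates. These sizes are
package defaults for the experiments, not method limits; all are plain
function arguments.

## 9. Known limitations

* Independent predictors and a correctly specified logistic outcome make
  the generator a *favorable* environment for logistic regression; on such
  cohorts the full-feature LR baseline sits near the Bayes ceiling, and no
  model selector — including this AutoML — can reliably beat the per-seed
  maximum of several near-optimal baselines evaluated on a 57-row test
  split, since that maximum tracks test-set noise. Comparative claims
  against baselines should therefore be read on cohorts where baselines
  are genuinely misspecified.
* Accuracy-based fitness at 31% prevalence is dominated by the majority
  class; stratified folds mitigate but do not remove this. A
  balanced-accuracy scorer would be a one-line change in `_raw_components`
  but is not the default, to keep the stated fitness form.
* The optimizer's strategy constants follow the behavioral contracts, not
  a published equation set; absolute benchmark scores are therefore not
  comparable to other implementations — only IBSLO-vs-BSLO relative
  comparisons are meaningful.
* The sampled interaction estimator scales as O(m²) model calls per
  coalition and is intended for small feature counts; use the XGBoost
  exact path for anything larger.
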