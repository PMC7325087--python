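# Methods

## The hybrid procedure

`shaplogit` operates on tabular data with a numeric design matrix `X`
(n samples × p predictors, p < n) and a binary outcome `y`. The model
families compared are:

* **L2 logistic regression** — `logit P(Y=1|x) = β₀ + β·x`, fitted by
  scikit-learn with penalty weight λ (`penalty_strength`, default 1;
  scikit-learn's `C` is `1/λ`). The returned `LogisticFit` always carries
  original-scale coefficients, so predictions are reproducible from the
  closed-form link regardless of internal standardization.
* **CART decision tree** and **random forest** — delegated to
  scikit-learn under the package's predictor contract (probabilities in
  [0,1]; labels are the 0.5-thresholded probabilities; the forest
  probability is the mean of per-tree leaf probabilities). The package's
  own entropy (bits), Gini impurity and information gain are the reference
  criteria and are cross-checked in the tests against an exhaustive
  best-split scan.

The hybrid pipeline (`fit_hybrid`) fits a forest on the training split,
computes its pairwise Shapley interaction tensor on a training subsample,
ranks unordered pairs by the sum of absolute per-sample attributions,
appends the top `k` pairs (or an elbow-selected prefix) as product columns
to both design matrices, and refits the logistic regression. Absolute
values are used in the global score because signed per-sample interaction
effects of a symmetric interaction cancel in expectation; saliency, not
direction, is what selects a candidate. Quadratic self-terms are excluded:
the candidates are interactions between distinct predictors.

## Shapley attributions

The coalition value is the interventional expectation
`v(S) = mean_b f(x_S, b_{M\S})` over a background set — by default a
seeded subsample of the training split (≤ 64 rows in the hybrid pipeline;
the brute-force API accepts any background). The model's **probability**
output is explained by default so attributions are comparable across model
families; the brute-force path also supports the log-odds (`margin`)
scale.

Two engines compute the same quantities:

* `exact_shapley` / `exact_interactions` enumerate all 2^p coalitions per
  sample. Off-diagonal entries are the Shapley interaction index halved
  across the two ordered pairs; the diagonal is defined as
  `phi_j − Σ_{k≠j} Phi_jk`, so every row of the per-sample matrix sums to
  the SHAP value and the tensor completes the additive explanation
  (`f(x) = E[f] + Σ_jk Phi_jk`). Hard caps p ≤ 12 (values) and p ≤ 10
  (interactions) keep the 2^p cost bounded.
* `tree_interactions` handles CART trees and forests with no cap on p.
  For a sample/background pair, each leaf restricts the coalition game to
  "features where only x satisfies the path must be in S; features where
  only the background row satisfies must be out; leaves failing both are
  unreachable". Each such game has closed-form Shapley and interaction
  values that depend only on the counts of required/forbidden features;
  the weights are tabulated with exact rational arithmetic and summed over
  leaves, trees and background rows. This is algebraically the same
  interventional game as the enumerator, so the two engines agree to
  floating-point round-off (asserted at 1e-4 elementwise on randomized
  fixtures; observed ~1e-16). The margin scale is rejected on ensembles
  because the ensemble log-odds is not additive across trees.

Numerical tolerances: local accuracy and row-sum consistency are asserted
at 1e-6; ranking ties are broken lexicographically by index pair, making
runs bit-reproducible; an interaction tensor asymmetric beyond 1e-6 is
rejected as corrupted rather than silently symmetrized.

## Inference on appended terms

The predictive fit is penalized (stabilizing the refit under the
collinearity a product column introduces, with columns z-scored internally
and coefficients mapped back to the original scale), while Wald p-values
per term come from a separate unpenalized maximum-likelihood refit —
penalized estimates have no standard Wald sampling theory. Under a null
interaction the appended coefficient is then non-significant at the usual
rates, which is the mechanism by which the procedure declines unwarranted
terms. If the unpenalized refit fails to converge (e.g. perfect
separation), p-values are reported as NaN rather than fabricated.

## Synthetic data

The generators are pure functions of their configuration (fixed seed ⇒
bit-identical output; logistic noise is drawn by inverse-CDF of a uniform
variate for cross-platform stability):

* **linear** — `Y = 1{3X₁ + ε > 0}`, `X₁ ~ N(0,1)`, `ε ~ Logistic(0,1)`:
  the log-odds are exactly linear, so logistic regression is the true
  model. Its Bayes accuracy is `E[σ(3|X₁|)] ≈ 0.836` (numerical
  integration, used as a test oracle).
* **nonlinear_interval** — `Y = 1{X₁ + 0.25ε ∈ (−6,−2.5) ∪ (0,1.5)}`,
  `X₁ ~ U(−10,10)`, `ε ~ N(0,1)`: prevalence 1/4; a monotone link defaults
  to the majority class while axis splits carve out the intervals.
* **interaction4** — `Y = 1{σ(ΣXᵢ + β·X₃X₄) > 0.5}` with `X₁..₃ ~ N(0,1)`
  and `X₄ ∈ {−0.5, 0.5}` with equal probability (symmetry). Since
  `σ(z) > 1/2 ⇔ z > 0`, labels are deterministic given the predictors —
  documented and tested by independent recomputation.
* **epistasis** — two causal biallelic loci coded {0,1,2} under
  Hardy–Weinberg equilibrium, trait = XOR of the carrier indicators, plus
  independent noise loci and a label-flip probability (default 0.1). The
  default minor-allele frequency is `1 − 1/√2 ≈ 0.293`, the value at which
  the carrier probability is exactly 1/2 and therefore each causal locus
  is exactly marginally independent of the trait (verified by exhaustive
  expectation over the nine genotype combinations). This is the canonical
  pure-epistasis setting: main-effects logistic regression scores at
  chance, a forest does not, and a single genotype-product column is
  linearly separable from the XOR classes — the ideal stress test for the
  hybrid. A MAF of 0.5 would leave carrier prevalence at 0.75 and leak
  strong marginal effects, defeating the purpose of the benchmark.

What the generators deliberately do not emulate: linkage disequilibrium
between loci, covariate correlation, measurement error in predictors,
class imbalance, and higher-than-pairwise interactions. Passing tests
therefore show that the machinery recovers planted pairwise structure
under clean sampling assumptions, not that it will rank interactions
correctly under, say, strong collinearity — in real data, correlated
predictors share interaction credit.

## Default study conditions

* Benchmark comparisons (single-predictor processes, sweep): n_train =
  n_test = 10,000 for the single-predictor processes and 5,000 for the
  four-predictor process, 10 replicate seeds — large enough that the
  family-level accuracies stabilize within about a percentage point.
  Model hyperparameters are the library's "naive" defaults (unbounded
  tree depth, 100 trees, √p feature subsampling), recorded per run in the
  manifest.
* Hybrid pipeline: internal forest of 100 trees, depth ≤ 5, ≥ 10 samples
  per leaf — pairwise structure surfaces in shallow trees and leaf count
  drives the explainer's cost; interaction tensor on ≤ 256 subsampled
  training rows against a ≤ 64-row background. The tests assert that the
  top-ranked pair on the planted-interaction processes is insensitive to
  these caps across seeds.
* Sweep: β grid 0..10 step 1, Savitzky–Golay smoothing with window 5 and
  polynomial order 2 (a ramp or quadratic passes through unchanged).
* Cross-validation is stratified (plain k-fold can produce single-class
  folds on imbalanced data); bootstrap intervals are percentile-method
  over 1000 joint label/score resamples, redrawing the rare single-class
  resample.
* Randomness: one user-facing seed per entry point, expanded into
  independent per-stage streams via `numpy.random.SeedSequence.spawn`
  (forest fit, row subsample, background subsample), so stages stay
  reproducible in isolation.

## Known limitations

* The interventional background treats predictors as independent when
  marginalizing; with strongly dependent predictors the hybrid may build
  off-manifold hybrid rows (the usual caveat of interventional SHAP).
* The elbow selector assumes one dominant score gap; rankings with a
  smooth decay select a single pair by construction.
* One extraction pass only: no iterative re-extraction after refitting,
  and no nonlinear single-variable transformations — the scope is
  pairwise product terms.
* `tree_interactions` scales as (leaves × path-feature-pairs × explained
  rows × background rows); very deep forests on large backgrounds are
  better explained on subsamples, which is what the pipeline defaults do.
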