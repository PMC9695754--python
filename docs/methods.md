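# Methods

## Model

Gene regulation is modelled per target gene as a varying-coefficient linear
model.  For expression of `p` regulator genes `x_1 .. x_p` and of target
gene `y_l`, the effect of regulator `j` on target `l` in sample `alpha`
depends on that sample's *modulator* value `m_alpha` (a per-sample cancer
characteristic such as drug sensitivity):

    y_il = sum_j beta_jl(m_alpha) x_ij + eps_il,   eps ~ N(0, sigma^2).

A nonzero `beta_jl(m_alpha)` is a directed edge `j -> l` in sample alpha's
network, so the fitted model is a stack of n sparse p x q networks indexed
by the modulator.  Estimation is local: for each target sample alpha the
coefficients solve a kernel-weighted L1-type regression,

    min  1/2 sum_i w_i(alpha) (y_il - b0 - x_i . beta)^2 + P(beta),

with `P` a ridge, lasso (default) or elastic-net penalty and weights
`w_i(alpha)` from one of three kernels over the modulator:

* **constant**: `w_i = exp(-(m_i - m_alpha)^2 / b)` with a fixed bandwidth
  `b`.  The denominator is `b` itself, not the textbook `2 b^2` — map
  bandwidths from other software accordingly.
* **adaptive (KNN)**: `w_i = exp(-(m_i - m_alpha)^2 / (b_alpha r(M)))` with
  `b_alpha = (m_alpha - m_alpha^kth)^2` the *squared* difference to the
  target's k-th nearest neighbour among the other samples.  The adaptive
  bandwidth widens automatically where the modulator distribution is
  sparse, fixing the constant kernel's failure mode there (with a constant
  bandwidth a rare-characteristic sample receives meaningful weight from
  only a handful of neighbours, leaving far too little data to select
  edges).  The squared form is used deliberately even though the quantity
  is often described as a Euclidean distance; with the dispersion factor
  `r(M)` (default: the modulator range max-min) the product `b_alpha r(M)`
  has the right units of a squared bandwidth either way, and the squared
  form is what makes sparse-region kernels widen superlinearly with
  isolation.  Ties in neighbour distance break by sample order; if k
  samples share the target's modulator value the bandwidth is floored at
  `epsilon_floor` (default 1e-8).  Default `k = ceil(sqrt(n))`.
* **multivariate**: for h characteristics jointly,
  `w_i = |H|^{-1/2} exp(-1/2 d^T H^{-1} d)`, `d = m_i - m_alpha`, with an
  SPD bandwidth matrix H (default: diagonal Scott's rule,
  `H_dd = (n^{-1/(h+4)} sd_d)^2`).  The determinant prefactor is kept, so
  weights may exceed 1; it cancels in the per-fit weight rescaling, which
  is why a single characteristic with `H = (b)` reproduces the constant
  kernel at bandwidth `2b`.

### Fitting choices

* Weights are rescaled to sum to n before each fit so a single lambda grid
  is comparable across target samples whose raw kernel masses differ by
  orders of magnitude between dense and sparse regions.  Scaling weights
  and lambda jointly by any c > 0 leaves the optimum unchanged.
* Predictors are standardized internally to weighted unit variance and the
  response weighted-centred; an intercept is always fitted (expression
  data are not assumed centred) and coefficients are returned on the
  original scale.
* The solver is cyclic coordinate descent (tolerance 1e-7 on the maximum
  standardized-coefficient change, at most 1e5 passes).  Coefficients
  below 1e-10 (standardized scale) are set to exactly zero; they are
  floating-point residue of the soft-threshold boundary, not edges.
* When a gene appears in both the regulator and the target list, the
  self-loop `j -> j` is excluded from that target's predictors.
* An edge exists iff its fitted coefficient is nonzero; no
  post-thresholding.

### Lambda selection

`lambda` is chosen on a geometric 30-point grid from the smallest
all-zeroing value downward (ratio 1e-3), by weighted BIC (default) or
weighted k-fold CV.  Two refinements matter for kernel-weighted fits:

* the information scale of the BIC is the Kish effective sample size
  `(sum w)^2 / sum w^2`, not the nominal n — a local fit in a dense
  modulator region may carry the information of only a few dozen
  independent samples;
* each candidate active set is scored by the RSS of its weighted OLS
  *refit* (relaxed-lasso scoring), not the shrunken lasso RSS.  Scoring
  shrunken fits biases information criteria toward small lambda and dense
  supports, because at useful penalty levels the shrinkage itself inflates
  the RSS.

By default one lambda is selected per target gene — minimizing the BIC
summed over up to 10 anchor samples spread across the modulator
distribution — and shared by all target samples; per-(sample, target)
selection is available behind a flag at proportional cost.  Fits whose raw
kernel mass is below 10 are flagged in the diagnostics as unreliable
sparse-region estimates.

## Regulatory effects and consensus networks

The regulatory effect `r_{alj} = beta_jl(m_alpha) x_{alpha j}`
(coefficient times raw expression) turns each target's coefficients into
an n x p matrix `R_l`; these matrices are the per-sample feature
representation used by both downstream analyses.  Consensus summaries
report, per edge, the median coefficient over a chosen sample subset
(mean behind a flag); the median matches how edge strengths are usually
summarized within a phenotype group, and "strength" here means the
coefficient, not the effect.

## Sparse common component analysis

To interpret the q effect matrices jointly, the common components are the
orthonormal directions A maximizing `tr(A^T G A)` with
`G = sum_l R_l^T R_l`; for q = 1 this is exactly PCA.  Sparsity and
network structure enter through the surrogate loadings Theta in the
alternating scheme (Q is the symmetric PSD square root of G, computed by
eigendecomposition with negative eigenvalues clipped at zero; any square
root gives the same G-dependent quantities):

1. theta step, per component k:
   `min ||Q a_k - Q theta||^2 + lambda1 ||theta||_1
        + lambda2 sum_{j<s} (theta_j - theta_s)^2 W_js`,
   where `W_js` is the Jaccard similarity `|N_j n N_s| / |N_j u N_s|`
   between the regulators' neighbour sets (`N_j` = targets connected to j
   in at least one sample network; two empty sets score 0).  The fusion
   term equals `lambda2 theta^T L theta` with L the weighted graph
   Laplacian of W, so the step is a quadratic-plus-L1 program solved by
   coordinate descent (closed-form ridge-Laplacian solve when
   lambda1 = 0); solutions satisfy the subgradient optimality conditions
   to 1e-6.
2. A step: Procrustes update `A = U V^T` from the thin SVD of
   `Q^T Q Theta`.

A is initialized from the unpenalized principal components; the loop stops
when the sign-aligned, per-column-normalized Theta changes by less than
`tol` (default 1e-4, measured after normalization to avoid scale drift) or
after `max_iter` (200) iterations, in which case the model is returned
with `converged=False` and a warning.  Final loadings are
`theta_k / ||theta_k||` with a deterministic sign (largest-magnitude entry
positive); identically-zero columns are flagged rather than normalized.
`K = "auto"` picks the smallest K whose unpenalized components explain 80%
of `tr(G)`.  W spans the regulator genes, since loadings are
p-dimensional.

Known limitation: an unsigned fusion penalty pulls connected genes toward
*equal* loadings and therefore misbehaves when truly coupled genes carry
opposite-sign coefficients; sign-aware network penalties are a documented
extension point, not implemented.

## Edge-knockout importance

Samples are labelled drug *sensitive* (sensitivity strictly below the 5th
percentile) or *resistant* (strictly above the 95th); percentiles use
linear interpolation, which is worth remembering at small n, and the
middle samples are excluded.  A classifier — RBF-kernel SVM, random
forest, or a two-hidden-layer feed-forward network (ReLU hidden layers of
64 and 32 units, sigmoid output, early stopping; widths are package
defaults, only depth and activations are structural) — is trained on the
edge features (columns of the flattened effect matrices, standardized
inside each training fold), and its accuracy measured by stratified
k-fold CV (default k = 10) repeated N times (default 20) on fresh seeded
fold splits.  Each edge's importance is the two-sided p value of the
pooled two-sample t test between the N baseline accuracies and the N
accuracies after removing that edge's feature column (removed, not
zeroed, so the knockout model has genuinely one fewer input; fold seeds
are fresh per edge).  The pooled SD is the textbook
`sqrt(((N-1)s^2 + (N'-1)s'^2)/(N+N'-2))`; an unsquared/unrooted variant
circulating in some descriptions is available as `as_printed=True` for
comparison.  Degenerate cases: zero pooled SD yields T = 0, p = 1 at
equal means and T = +-inf, p = 0 otherwise.

Edges with raw p < 0.05 are flagged by default; Benjamini-Hochberg
adjustment is available behind a flag.  The baseline record is computed
exactly once and shared across all knockouts — both an algorithmic and a
determinism requirement.  Caveat: repeat-level CV accuracies share data
and are not independent draws, so the t test is a heuristic ranking
device; in null simulations its empirical type-I error at alpha = 0.05
stays near nominal (tolerably up to ~0.10).  Cost is one baseline plus
one model family per edge, i.e. (q x p) + 1 cross-validated fits in the
worst case — the dominant runtime of the full pipeline.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate the
structural features the methods are sensitive to, not real expression
data (no library-size effects, dropout, or heavy-tailed noise — passing
tests demonstrate correctness of the estimators under the stated model,
not performance on CCLE-like data):

* **modulator**: a two-component Gaussian mixture, weights (0.75, 0.25),
  means (4, 8), sds (0.5, 1.5) — a dominant dense region and a wide sparse
  one, the regime that separates adaptive from constant bandwidths.
* **varying-coefficient scenario** (defaults n = 300, p = 10, q = 5): per
  target, a linear edge `beta = 0.5 m`, a threshold edge
  `beta = 1.5 * 1[m <= 6]` vanishing above the cutoff between the mixture
  components, and a constant edge `beta = 1`; regulators iid standard
  normal (an exchangeable-correlation option exists for robustness
  checks); noise sd 1.8, giving a signal-to-noise ratio near 3.  The
  mixture sits away from zero so every true edge coefficient is bounded
  away from zero (min |beta| ~ 1): support recovery against ground truth
  is only a meaningful benchmark when the truth is detectable in
  principle.
* **common-structure scenario**: q matrices `R_l = S_l V^T + noise`
  sharing a sparse orthonormal loading matrix V (default support 10 of
  p = 50, noise sd 0.1); neighbour sets derived from the true support.
* **drug response**: a linear combination of designated causal-edge
  feature columns plus Gaussian noise, so percentile labelling yields
  classes separable exactly through those edges.

## Problem sizes in the shipped checks

The test suite and the results-reproduction script run the recovery
studies at n = 300 (10 and 3 seeds respectively), the common-component
recovery at p = 50 (10 / 3 seeds), and the knockout study with a
10-tree random forest, 5-fold CV and 8 repeats (10 power seeds / 20 null
seeds in the suite; 4 / 8 in the script) — sizes chosen so the full stack
re-runs from scratch in minutes on one core while leaving the measured
quantities' margins wide.

## Numerical notes

* Coordinate descent tolerances: 1e-7 (network fits), 1e-12 (theta step);
  both solvers are deterministic and independent of thread count, as is
  every pipeline output (threads only parallelize independent fits whose
  seeds are derived per-unit from the base seed).
* Gram square root: eigendecomposition with eigenvalues clipped at 0;
  `Q^T Q` reproduces G to ~1e-16 relative error.
* Degenerate inputs fail loudly and specifically: constant modulator
  (no range), zero-variance characteristics (no Scott bandwidth),
  all-zero or single-support kernel weights, constant response
  (intercept-only model with a warning), constant sensitivities (no
  percentile classes), fewer than 2 labelled samples per class.
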