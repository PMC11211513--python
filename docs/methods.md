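# Methods

## Model

`twingp` fits a pair of ε-offset bound functions to trait values y given
marker dosages X (rows samples, columns markers, ALT-allele counts in
{0,1,2}). With feature map φ (identity, or RBF kernel rows against the
training samples) and residual r = y − Hw − b (H the mapped design):

- down-bound side: J₁(w₁,b₁) = ½‖r − ε₁e‖² + (C₁/2)‖r + ε₁e‖²
  + (C₃/2)(‖α₁∗w₁‖² + b₁²)
- up-bound side:  J₂(w₂,b₂) = ½‖r + ε₂e‖² + (C₂/2)‖r − ε₂e‖²
  + (C₄/2)(‖α₂∗w₂‖² + b₂²)

with C₂ = C₁ and C₄ = C₃ tied throughout. The predictor is the bound
average ½(Hw₁ + Hw₂) + ½(b₁ + b₂). Each side is an unconstrained
strictly-convex quadratic at fixed α, so its minimizer is one symmetric
linear solve of size (p+1), p being the number of markers (linear) or
training samples (RBF). The ε column of the right-hand side carries the
factor (C₁−1) on the down side and (1−C₂) on the up side; both systems
are verified in the test suite against a generic numerical minimizer of
the objectives themselves, which is the ground truth we use for the
closed forms (the printed single-solve shortcuts for the unregularized
model are not used).

The L1 penalty on the weights is realized by iterative reweighting:
‖w‖₁ = ‖α∗w‖₂² when αᵢ = 1/|wᵢ|, so the algorithm alternates exact
solves of the two systems with the update αᵢ ← 1/max(|wᵢ|, 10⁻⁸). The
absolute value is required for D = diag(α)² to act as an L1 surrogate;
the floor guards division by zero and caps α at 10⁸. The bias enters the
regularizer too (the bottom-right diagonal entry carries C₃), so a pure
bias model shrinks slightly toward zero — visible only when C₃ is large
relative to n.

### Convergence and numerics

- α initialization: all-ones by default (deterministic and scale-neutral);
  a seeded Uniform(0.5, 1.5) option exists. With C₃ = 0 the α-dependent
  block vanishes, the model reduces exactly to plain LSTSVR and a single
  solve per side is returned (the reduction is asserted to 1e-8 relative
  in the tests, for any α initialization).
- Stopping rule: max relative α change max|α⁺−α|/(1+|α|) < 1e-4, or 50
  iterations; the results object records the iteration count and a
  convergence flag. Near the sparsity boundary α oscillates between the
  floor cap and finite values, so non-convergence at 50 iterations can
  occur with aggressive C₃; the returned solution is still the exact
  minimizer at the final α.
- Linear algebra: Cholesky factorization with one retry after adding
  ridge jitter 1e-10·trace/dim — needed both when weights hit the α floor
  (D entries ≈ 10¹⁶) and when p > n with C₃ = 0 (rank-deficient normal
  matrix); a second failure raises with diagnostics.
- Degenerate inputs: constant phenotypes are accepted (the model
  collapses to its bias); zero-variance markers are retained and receive
  near-zero weights under C₃ > 0.

### Kernel form

The RBF map is K(x,x′) = exp(−‖x−x′‖²/2σ²), computed with scikit-learn's
pairwise distances; H = K(X, X_train) with no appended ones column — the
bias is an explicit parameter. Kernel models keep a reference to the
training genotypes for prediction and serialize it in the model
container.

## SABO hyperparameter search

SABO is a population metaheuristic: agent i's displacement is the
arithmetic mean over j of sign(F(Xᵢ)−F(Xⱼ))·(Xᵢ − v∗Xⱼ), scaled by a
random r ∈ [0,1] per agent; a proposal replaces the agent only on strict
improvement, so the best-so-far fitness is non-increasing and the
evaluation budget is exactly N(T+1). Unspecified distributional details
are fixed as: v components drawn uniformly from {1, 2} (a continuous
Uniform[1,2] option exists), fresh v per (i,j) pair and fresh r per agent
each iteration, and clamping to the bounds after displacement (keeping C
and σ positive).

Search dimensions are (C₁, C₃, σ) — two for the linear kernel — on
log₁₀ scales, since all three act multiplicatively. Defaults: C₁ ∈
[10⁻³, 10³], C₃ ∈ [10⁻⁴, 10²], σ ∈ [10⁻²√m, 10²√m]; the σ range tracks
√m because squared distances between dosage vectors grow linearly with
the number of markers. Positions are stored in natural units but all
SABO arithmetic runs in the transformed (log) space, which is what makes
the subtraction average meaningful for multiplicative parameters.
Defaults N = 20 agents, T = 50 iterations; the tuning fitness is the
inner cross-validated MSE (5-fold by default; a single 75/25 holdout
mode trades variance for a 5× speedup).

ε₁ = ε₂ = 0.05 are fixed defaults, exposed but not searched. The two
bound objectives coincide — hence w₁ = w₂ — exactly when ε₁ = ε₂ = 0
(any C) or when ε₁ = ε₂ with C = 1; for other C the two sides weight the
±ε-shifted residuals differently by design.

## Evaluation protocol

Accuracy is the Pearson correlation between observed and predicted trait
values, plus MSE, averaged over the folds of a (replicated) k-fold
cross-validation with k = 10 by default; replicate r re-partitions with
seed + r. Phenotype standardization (n−1 denominator) is fit on each
training partition and applied to its validation fold, so reported MSE
is on the z-scale and no held-out statistics leak into training; a
global-standardization mode reproduces the simpler protocol. Tuning is
nested — SABO sees only the outer training partition — and a canary test
asserts that perturbing held-out phenotypes leaves the tuned
hyperparameters unchanged. Fold PCC is left undefined (an error, not
zero) for constant inputs.

## Synthetic data

The generator emulates the target regime: per-marker allele frequency
pⱼ ~ Uniform[maf_low, maf_high], dosages Binomial(2, pⱼ) i.i.d. across
samples (Hardy–Weinberg, no linkage disequilibrium), and an additive
trait g = Σ βⱼxⱼ over n_qtl causal markers (optionally plus pairwise QTL
products), with Gaussian or Laplace effects. Environmental noise is
residualized against g in-sample and rescaled so the realized
Var(g)/Var(y) equals the target h² exactly — exact finite-n control
rather than expectation-level calibration, which is what makes the
heritability tests sharp. h² = 0 yields a pure-noise standard-normal
trait. An optional block-LD mode (markers within a block threshold
shared latent gametes) exists for stress tests.

What the generator does *not* emulate matters for interpreting results:
real SNP panels have extensive LD, population structure and
minor-allele-frequency spectra that this i.i.d. sampler lacks. LD in
particular reduces the effective marker dimension and is the main reason
kernel methods perform well on real crop panels; under the no-LD default
with sparse architectures, distance-based kernels see mostly non-causal
markers and behave like ridge regression, so their accuracy sits well
below the additive ceiling √h² while marker-sparse linear models (C₃ in
the linear form) get much closer. Passing tests therefore demonstrate
correctness of the machinery, not real-data accuracy levels.

## Problem sizes

The shipped analyses use sizes chosen to exercise the n ≪ m regime while
staying desk-scale: the end-to-end tuned pipeline runs n = 200, m = 1000,
h² = 0.7, 20 QTL with SABO budgets N = 10, T = 15 and nested 5-fold
tuning inside 10 outer folds (~1.5 min); calibration studies use 20
seeds at n = 2000 (heritability) and n = 60 (null traits). The
`highdim_smalln` fixture (n = 100, m = 5000) exercises the p ≫ n linear
solver path.

## Known limitations

- The reweighted L1 scheme is a heuristic majorization: each alternating
  solve is an exact minimization at fixed α (monotone per-side surrogate
  descent, tested), but no global-convergence guarantee exists and the
  α floor bounds the achievable sparsity resolution.
- The kernel form penalizes per-sample dual weights, so it cannot select
  markers; marker sparsity is only available in the linear form.
- SABO is stochastic and derivative-free; with small budgets the tuned
  MSE varies across seeds. All entry points are seeded and bit-reproducible.
- No PLINK/HDF5 backends, no multi-trait or G×E models, no baseline
  learners (ridge/BLUP/Bayesian regressions); a user can plug external
  regressors into the CV harness by wrapping them in the fit/predict
  interface.
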