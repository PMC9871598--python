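# Methods

## Model

Each subject contributes a time-series matrix `X ∈ ℝ^{T×N}` (T time
points, N ROIs), centered and L2-normalized per column so that `XᵀX` is
the Pearson correlation matrix. The sparse-representation (SR) network
solves, column by column,

    min_w ‖x_i − Σ_{j≠i} w_ij x_j‖² + λ₁ Σ_{j≠i} |w_ij| ,

equivalently `min_W ‖X − XW‖_F² + λ₁‖W‖₁` with `w_ii = 0`. The noise
model replaces the implicit i.i.d. residual assumption with a Gaussian
residual whose T×T precision `Ω` is *shared across ROIs*: one noise
pattern over time, not one per region. The joint negative
log-likelihood plus priors is

    L1 prior:      tr[(X−XW)ᵀΩ(X−XW)] − N ln|Ω| + λ₁‖W‖₁ + λ₂‖Ω‖₁
    Wishart prior: tr[Ω((X−XW)(X−XW)ᵀ + αI)] − (N+ν) ln|Ω| + λ₁‖W‖₁

(the Wishart prior has scale matrix `α⁻¹I`, an increasingly broad prior
as α→0, and ν degrees of freedom, ν > T−1; its normalizing constant
does not depend on Ω and is dropped).

Both objectives are minimized by exact alternating (block-coordinate)
minimization from `Ω = I`:

1. **W-step.** With `Y = Ω^{1/2}X`, the W-subproblem is exactly
   `min_W ‖Y − YW‖_F² + λ₁‖W‖₁`, an ordinary column-wise lasso on the
   whitened data. `Y` is deliberately *not* re-centered or
   re-normalized — the quadratic-form identity must hold exactly, and
   re-normalizing would silently change the effective penalty per
   column.
2. **Ω-step.** On the residual `R = X − XW`: under the L1 prior, a
   graphical lasso applied to `S/N` with penalty `λ₂/N`
   (`S = RRᵀ`); under the Wishart prior, the closed-form posterior
   mode `Ω = (N+ν)(S + αI)⁻¹`.

Because each step is an exact minimizer of the joint objective over its
block, the objective trace is non-increasing (verified over random
instances to 1e−8 relative slack). Iteration stops when the relative
objective change drops below `outer_tol`, or at `max_outer_iter` with a
warning. One iteration from `Ω = I` reproduces plain SR exactly; the
same holds for PCAND versus PC.

**PCAND** plugs the identical whitening module into the correlation
estimator (`W = YᵀY`). It has no written joint objective of its own; we
reuse the configured prior's likelihood term (λ₁ = 0) for the stopping
rule, note that the correlation step is not that objective's exact
W-minimizer, and therefore make no monotonicity claim — on unstructured
data PCAND frequently runs to the iteration cap, which is reported via
`converged_`.

## Numerical choices

- **Lasso.** scikit-learn coordinate descent with
  `alpha = λ₁/(2T)`, mapping its `1/(2T)`-scaled objective onto the
  unnormalized one so λ₁ keeps its published scale; on unit-norm
  columns every λ₁ ≥ 2 exceeds the activation threshold
  `2·max|x_jᵀx_i|` and returns the exact zero network. The diagonal
  constraint is structural (ROI i is excluded from its own design
  matrix). Defaults: `lasso_tol = 1e−6`, `lasso_max_iter = 10000`;
  non-convergence raises rather than silently continuing. λ₁ = 0 falls
  back to least squares via `lstsq`.
- **Graphical lasso.** The Ω-subproblem's empirical covariance `S/N`
  has rank ≤ N ≪ T, and off-the-shelf coordinate-descent graphical
  lasso implementations break on such rank-deficient inputs (sklearn's
  raises "Non SPD result"). We therefore solve it with ADMM: the
  smooth subproblem is solved exactly per iteration through one
  eigendecomposition (every iterate positive definite by
  construction), the L1 subproblem by soft thresholding with the
  *diagonal included* in the penalty, with residual balancing for the
  ADMM penalty parameter and combined absolute/relative stopping
  (defaults `tol = 1e−7`, `max_iter = 10000`). On well-conditioned
  problems the solution agrees with sklearn's graphical lasso to
  ~1e−4 relative, and sklearn serves as an independent cross-check in
  the test suite.
- **Ω scale coupling and `omega_rescale`.** Both Ω updates carry a
  large overall scale: the Wishart mode scales with `N+ν`, and the L1
  solution's eigenvalues on the null space of S grow like `N/λ₂`.
  That scale multiplies `Y = Ω^{1/2}X` and *shrinks the effective λ₁*
  of the next W-step — at T ≫ N the faithful update densifies W
  drastically. `omega_rescale=True` renormalizes Ω to trace T after
  each update, keeping the estimated noise *shape* while pinning its
  scale to the identity initialization's. The default is the faithful
  (unrescaled) update, matching the literal objective; the rescaled
  variant is what we use in the recovery experiments and is reported
  as a departure wherever it is used.
- **Wishart hyperparameters.** `ν = T` by default (the smallest
  integral value satisfying ν > T−1) and `α = 1`. α must be strictly
  positive: `S` has rank ≤ N < T in the standard regime, so the
  "infinitely broad" limit α→0 is ill-posed.
- **SPD square root** by eigendecomposition, clipping eigenvalues in
  `[−1e−10, 0)` (relative to the largest) to zero; genuinely
  indefinite inputs raise.
- **Degenerate inputs.** Constant ROI columns are rejected at
  normalization (named by index); matrices smaller than 2×2 are
  rejected; Ω that is not positive definite raises wherever a
  log-determinant is needed.
- **Symmetrization.** Regression networks are asymmetric; they are
  symmetrized as `(W + Wᵀ)/2` only at feature-extraction/scoring time,
  never inside the optimization.

## Classification pipeline

Features are the upper-triangle edge weights (4005 for N = 90).
Selection is an equal-variance two-sample t-test at `p < 0.01` (Welch
available behind `equal_var=False`); features with degenerate
statistics are never selected; if nothing passes, the 10 smallest-p
features are used so every fold stays classifiable. The classifier is
a linear SVM, C = 1, no class weighting, no additional
standardization. Evaluation is leave-one-out; the sparsity parameter
is chosen per outer fold by an inner LOOCV over
{0.05, …, 1.00} on accuracy, ties to the smallest λ (sparser model),
with t-test selection re-run inside every inner fold (the stricter
protocol). Network estimation is per-subject and label-free, so
networks are cached per (subject, λ) — mathematically identical to
re-estimating inside each fold. No information from a held-out subject
reaches selection or fitting.

## Synthetic data

The generator mirrors the estimators' own assumptions so that ground
truth is well defined:

- a sparse symmetric ROI precision (each pair an edge with probability
  `edge_density`; magnitudes U(0.3, 0.6), random sign; strict diagonal
  dominance, then rescaled so the implied covariance has unit
  diagonal — standardized "BOLD-like" clean signal, making
  `noise_scale` a noise-to-signal SD ratio);
- clean rows i.i.d. over time from `N(0, inv(precision))`;
- additive noise `σ·L·Z` with `L` the Cholesky factor of an AR(1)
  covariance `ρ^{|t−s|}` shared by all ROI columns — the simplest
  temporal family whose precision is sparse (banded), matching the L1
  noise prior's rationale; an arbitrary SPD covariance can be
  substituted;
- group effects injected on the *precision* scale (SR-family
  estimators target partial correlation): `n_effect_edges` pairs
  outside the support receive ±`effect_size` in the patient group,
  with diagonal-boosting repair if positive definiteness is lost.

What it does **not** emulate: hemodynamic response convolution,
scanner drift, motion artifacts, spatially correlated noise, or
between-subject heterogeneity of the network. Passing recovery and
pipeline tests therefore demonstrate internal consistency of the
estimators under their own noise model, not performance on real fMRI.

## Experiment sizes and observed behavior

Recovery experiments run at N = 15 ROIs, T = 120 time points, edge
density 0.1, ρ = 0.6, σ = 0.5, λ₁ = 0.3, λ₂ = 0.1, 20 replicate
seeds; classification sanity runs use 15 + 15 subjects with a strong
(0.8) precision effect on 20 edges. Three findings worth recording:

- An oracle run that substitutes the *true* error precision into the
  W-step beats plain SR on edge-support F1 (≈ 0.62 vs 0.56) and ties
  it exactly under i.i.d. noise — the whitening principle is sound in
  this generator.
- With Ω *estimated*, N = 15 residual vectors must determine a
  120×120 precision; the estimation noise costs more than the
  whitening gains at this scale, and SRAND-L1's mean F1 lands slightly
  below SR's (≈ 0.53–0.54 vs 0.54–0.56 across seed sets) while
  producing markedly sparser networks (≈ 14 vs 19 nonzero edges
  against ≈ 11 true). In the regime the method was designed for the
  ratio N/T is four times higher, making Ω far better determined.
- Leave-one-out on label-permuted or null cohorts is pessimistically
  biased: with balanced groups the training fold always contains one
  fewer subject of the held-out subject's class, and a linear SVM on
  uninformative features then leans toward the training majority, so
  null accuracies fall below 0.5 (sometimes to 0) rather than
  scattering around it. This is a known LOOCV artifact, not a leakage
  sign; the permutation sanity check uses a ±0.25 band around chance
  accordingly.

## Known limitations

- The faithful (unrescaled) SRAND-L1 update is practically unusable
  when T ≫ N (see scale coupling above); use `omega_rescale=True` or
  the Wishart prior there.
- PCAND convergence is heuristic (no descent guarantee).
- The ADMM graphical lasso targets the elementwise-L1 objective
  including the diagonal; diagonal entries are therefore slightly
  shrunk relative to an off-diagonal-only penalty.
- LOOCV accuracy estimates on small cohorts carry high variance and
  the pessimistic null bias described above; interpret single-cohort
  accuracies cautiously.
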