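# Methods

## Model

`g3cs` selects genes from an expression matrix **X** ∈ ℝ^{m×n} (m genes in
rows, n samples in columns) without using sample labels. It minimizes

  J(P, F, Z) = ‖PᵀX − FZᵀ‖²_F + α‖P‖₂,₁ + β·Tr(Pᵀ M̄ P) + γ·Tr(Zᵀ L Z)

subject to FᵀF = I, ZᵀZ ≈ I and Z ≥ 0, where P ∈ ℝ^{m×c} projects genes
into a c-dimensional pseudo-label space, Z ∈ ℝ^{n×c} is a relaxed
nonnegative cluster indicator for the samples, and F ∈ ℝ^{c×c} aligns the
two. Gene i's importance is ‖Pⁱ‖₂ (the row ℓ₂-norm); the ℓ₂,₁ penalty
makes most rows vanish so this ranking is sparse and stable.

The two data-structure matrices are built once per fit:

* **Gene redundancy, M̄.** M is the gene-pair covariance across samples
  with the unbiased 1/(n−1) denominator (a constant gene yields a zero
  row/column). M̄ aggregates it: in the default "printed" reading the
  diagonal keeps M_ii and every off-diagonal entry of row i becomes
  Σ_{k≠i} M_ik; the alternative "diag-rowsum" reading puts that sum on the
  diagonal and keeps the off-diagonal covariances. Because the quadratic
  form only senses the symmetric part, M̄ is symmetrized by default so the
  gradient 2M̄P used in the P-step is exact.

* **Sample geometry, L.** S_ij = exp(−‖x_i − x_j‖²/(2t²)) on pairs where
  either sample is among the other's k nearest Euclidean neighbors
  (k = 5, t = 0.5 by default), zero elsewhere and on the diagonal;
  neighbor ties at the k-th distance break toward the smaller sample
  index. L = D − S is the unnormalized Laplacian, so
  Tr(ZᵀLZ) = ½ΣΣ‖z_i − z_j‖²S_ij pulls graph-adjacent samples toward the
  same soft cluster.

## Optimization

Block coordinate descent, one "sweep" = P-block, F-step, Z-step:

* **P (closed form, inner loop).** For fixed F, Z the nonsmooth ℓ₂,₁ term
  is majorized by the standard reweighting: G = diag(1/(2·max(‖Pⁱ‖₂, ε)))
  with floor ε = 1e−8, giving the linear system
  (XXᵀ + αG + βM̄_sym) P = XZFᵀ. G and P are re-alternated inside the
  sweep (up to 15 iterations, stopping when P moves by < 1e−7 relative),
  which is what makes single sweeps productive enough for the outer loop
  to stop in a handful of iterations. A singular system (only possible at
  α = β = 0) is ridge-stabilized with a warning.

* **F (exact Procrustes).** With Z near column-orthonormal the F
  subproblem reduces to min ‖W − F‖_F s.t. FᵀF = I with W = PᵀXZ, solved
  exactly by the polar factor UVᵀ of W's SVD. A literal penalty-gradient
  assignment F_ij = W_ij/[F + ρ(FFᵀF − F)]_ij (ρ = 1e3, sign-preserving
  denominator floor 1e−12) is retained behind `f_method="multiplicative"`
  for fidelity experiments; the Procrustes path is the default and the
  only one used by `fit`.

* **Z (damped multiplicative KKT step).** The orthonormality constraint is
  enforced by a penalty (κ/4)‖ZᵀZ − I‖²_F; the KKT conditions of the
  penalized subproblem yield a multiplicative update whose numerator
  collects 2(XᵀPF)⁺ + 2γSZ + κZ and whose denominator collects
  2(XᵀPF)⁻ + 2ZFᵀF + 2γDZ + κZZᵀZ (the Laplacian gradient is split as
  L = D − S so both sides stay nonnegative; the signed regression gradient
  is split into positive/negative parts likewise). The raw ratio is
  **square-root damped** (Z ← Z·√(num/den)): the undamped column-norm map
  behaves like s ↦ 1/s when the κ term dominates and oscillates with
  period 2, while the damped map has identical fixed points and converges.
  This is the same damping used for orthogonal nonnegative matrix
  factorizations. Zeros of Z are absorbing, which is why the initializer
  never produces exact zeros.

* **Initialization (seeded, deterministic).** Z starts from k-means on the
  leading c eigenvectors of S, converted to a hard indicator and
  column-normalized — exactly column-orthonormal by construction — then
  shifted by +1e−4 to unlock the multiplicative update. The shift is the
  only initial orthonormality violation, and keeping it small is what
  keeps the early sweeps monotone: the κ penalty otherwise trades
  objective value for constraint repair. F starts at I; P comes from one
  closed-form solve with unit row weights (G = I/2), since row norms are
  undefined before P exists.

* **Stopping.** The objective is recorded at initialization and after
  every sweep; the loop stops when |J_t − J_{t−1}|/max(J_{t−1}, 1e−12) <
  tol (default 1e−5) or after max_iter = 200 sweeps. On the default
  synthetic data convergence typically takes 5–20 sweeps.

Monotone descent of J is an empirical property, not a theorem: the F-step
is exact only up to Z's (small) orthonormality violation and the Z-step
descends the penalized, not the raw, objective. The test suite asserts it
with relative slack 1e−6 from sweep 2 onward across 20 seeds.

## Defaults and what they mean

| parameter | default | role |
|---|---|---|
| α | 10 | row-sparsity weight; with m ≫ n the regression can fit cluster indicators with chance correlations from pure-noise genes, and a strong ℓ₂,₁ weight is needed before the ranking concentrates on genuinely predictive genes |
| β | 1e−3 | gene-covariance (redundancy) weight; **scale-dependent** — M̄ carries squared expression units and its symmetric part is indefinite, so large β makes the P-system lose positive definiteness and the objective unbounded below. The default is deliberately conservative; the evaluation grid explores 1e−3…1e3 |
| γ | 1 | manifold weight |
| c | — | number of sample clusters; defaults to the number of distinct labels when labels are supplied for evaluation, otherwise user-provided |
| k, t | 5, 0.5 | neighbor count and kernel width of the sample graph |
| κ | 1e4 | Z-orthonormality penalty; large enough that Z stays near-orthonormal throughout (final ‖ZᵀZ−I‖_F ~ 1e−3) — smaller values (1e2–1e3) leave a slowly drifting tail that can exhaust max_iter |
| ρ | 1e3 | F-orthogonality penalty, used only by the multiplicative F variant |
| ε | 1e−8 | row-norm floor in G |
| tol, max_iter | 1e−5, 200 | stopping rule |

No normalization is applied to the input by default (a per-gene
standardization flag exists): silent transforms would change M and S.
Missing values are rejected, not imputed.

## Synthetic data

The generator emulates exactly the structure the model assumes: n = 60
samples in c = 3 near-equal contiguous clusters; 10 informative genes,
each drawing a ±(effect_size = 2) mean per cluster with at least one
between-cluster sign contrast; 20 redundant genes, each a randomly chosen
informative parent plus N(0, 0.1²) perturbation; 170 noise genes
N(0, 1). Gaussian noise throughout (log-scale microarray intensities are
approximately Gaussian); everything is a deterministic function of the
seed.

What it does **not** emulate: probe-level artifacts, batch effects,
heavy-tailed or count noise, missingness, unequal cluster sizes, and
genes correlated with noise rather than with informative genes. Passing
tests therefore show the machinery behaves as designed under its own
assumptions, not that it wins on any particular real dataset.

A consequence worth stating plainly: with perturbation sd 0.1 against
unit noise, a redundant gene is statistically almost indistinguishable
from its parent, and no unsupervised criterion can systematically prefer
the parent. The selector reliably fills its top ranks with
*signal* genes (informative or redundant — measured signal precision 1.0
over the hyperparameter grid) and the covariance penalty reliably demotes
*correlated groups as a whole*, but which member of a parent/copy group
survives is close to a coin flip, so precision counted against the
informative set alone plateaus near E[1/(1+#copies)] ≈ 0.4.

## Evaluation harness

Classifiers enter only through an opaque fit/predict contract (thin
adapters for kNN, linear SVM and random forest are provided). Accuracy is
repeated stratified 5-fold cross-validation: a fresh fold partition per
repeat, mean over all 25 fold accuracies, sd over the 5 repeat means.
Gene selection is performed once on the full data *before* fold
splitting, mirroring the common published protocol; this optimistically
biases accuracy, and the unbiased selection-inside-folds variant is left
to the caller by refitting per fold. The grid harness reports, per gene
count, the best result over the α, β, γ grid (optimal-parameter
protocol), so best-over-grid dominates every fixed member by
construction.

## Problem sizes

All shipped tests and the acceptance script run on the 200 × 60 synthetic
default (or smaller): 20-seed solver batteries, a 3×3×3 grid over 10
seeds for recovery, 10 seeds for the redundancy shift, and 5×5-fold CV on
30–60 samples. These sizes give stable averages for the behavioral
fractions while keeping a full run in the minutes range.

## Known limitations

* The adjusted-correlation matrix M̄ (either reading) is indefinite in
  general, so for large β the objective is unbounded below and the
  alternating scheme oscillates instead of descending; the package leaves
  such configurations reachable (the evaluation grid uses them for
  ranking only) but the descent guarantees documented above hold in the
  α-dominated regime.
* c must be chosen by the user when no labels exist; the method offers no
  internal model selection for it.
* The multiplicative F variant is a literal fidelity path, not a
  recommended solver.
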