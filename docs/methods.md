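# Methods

## Data model

The universal input is a beta-value matrix (samples × CpGs, values in
[0, 1], no missing values — imputation is upstream preprocessing) with an
aligned phenotype table. Capsules are named, ordered lists of CpG ids; a
CpG may belong to several capsules (a CpG annotated to two genes
contributes to both). Capsule maps serialize as two-column TSV
(capsule, cpg) for portability; beta/phenotype tables as TSV/CSV.

## Capsule construction

Capsules come from four sources: distinct values of an annotation column
(composite `;`-delimited fields contribute the CpG to every named context),
fixed-width genomic windows, gene sets layered on gene capsules, and custom
mappings. Genomic coordinates are 0-based half-open (BED convention); a bin
`[start, start+width)` is tiled every `step` bases from 0 and a CpG joins
every overlapping bin, so a CpG at position `start+width` belongs to the
next bin, not this one. The minimum-CpG filter keeps capsules with
*strictly more than* `min_cpgs` CpGs (default 5, i.e. "more than five");
because the right threshold is data-dependent it is exposed as a parameter
and included in the randomized hyperparameter search space.

## Synthetic data generator

The generator emulates the salient features of bulk methylation arrays:

- **Bimodality.** Each background CpG's latent mean is drawn from a
  two-component Beta mixture (defaults Beta(2, 8) and Beta(8, 2), equal
  weight), concentrating means near 0.2 and 0.8 as on real arrays.
- **Per-sample noise.** Values are drawn from Beta(mν, (1−m)ν) around the
  latent mean m with concentration ν = 50, giving a per-CpG SD of roughly
  0.05–0.07 — comparable to technical-plus-biological spread within a
  class on real arrays.
- **Capsule-coherent class signal.** Each of the designated signal capsules
  carries a ±1 direction per class (deterministic codewords whose first
  ⌈log₂ n_classes⌉ columns already separate all classes); every CpG of a
  signal capsule has class means at base ± δ/2, so the between-class gap is
  exactly the effect size δ. Signal-capsule base means are drawn uniformly
  from [0.3, 0.7] so the shifted means stay inside (0, 1); an infeasible
  combination raises an error rather than clipping silently.

The default conditions — 4 classes, 150 samples per class, 20 capsules of
10 CpGs, 5 signal capsules, δ = 0.3 — are the study setting used by the
test suite and the acceptance script (a 50-capsule variant is used for
support recovery). What the generator does **not** emulate: batch and dye
bias, detection-p-value artifacts, probe-type chemistry differences,
covariate structure, or spatial correlation along the genome beyond capsule
membership. Passing tests therefore demonstrate correctness of the
machinery and recoverability of capsule-aligned signal, not robustness to
array-specific technical artifacts.

## Capsule network

Per-capsule encoders are MLPs (default one hidden layer of 32, ReLU,
linear output, embedding dimension 8). The transform stage uses **per-
(child, parent) matrices** W_ij (output dimension 16): with a single
transform shared across parents, every parent receives identical
predictions, the agreement update is symmetric across parents, and routing
provably never leaves the uniform coupling — a degenerate model. The shared
variant is retained behind `shared_transform=True` purely for ablation, and
a regression test asserts its couplings stay exactly uniform.

Routing logits are re-initialized to zero on every forward pass (they are
iteration state, not parameters); 3 iterations by default. Margin-loss
constants are m⁺ = 0.9, m⁻ = 0.1 with down-weight 0.5, the conventional
values for routing-by-agreement capsule models; the reconstruction weight
defaults to 0.005 so the margin term dominates. The decoder is an MLP from
the true-class output capsule (predicted class at inference) to the full
input CpG vector, trained only through the reconstruction term. Prediction
is the argmax of output-capsule norms; exact ties resolve to the lowest
class index for determinism.

**Gradients.** Both models are pure NumPy with hand-derived reverse-mode
gradients and an Adam optimizer (default lr 1e-3 generally; the training
examples use 2e-3/5e-3). In the capsule network the routing coefficients
are treated as constants during the backward sweep — gradients flow through
the final weighted sum, the squash Jacobian
(J = κI + (κ′/‖s‖) s sᵀ, κ = ‖s‖/(1+‖s‖²)), the affine transforms, the
encoders and the decoder. Finite-difference tests verify every gradient
path (with fixed couplings for the capsule model).

## Sparse pathway network

The aggregation nonlinearity σ defaults to the identity, keeping z_j
interpretable as a weighted-mean-like summary (tanh and ReLU are available
in config). Weights initialize at 1/d_j plus small jitter, i.e. near the
mean-beta summary. The group-L1 penalty Σ_j √d_j ‖w⃗_j‖₂ is applied as a
differentiable loss term with an ε = 1e-8 guard on the norm in its
gradient, rather than a proximal step: weights approach but do not hit
exact zero, so "dropped out" genes are reported by the documented threshold
‖w⃗_j‖₂ < 1e-4. CpG rankings (ascending, descending, and by absolute
weight) break ties lexicographically by CpG id; gene importance can be
ranked by maximum absolute CpG weight or by group norm.

## Training utilities

Splits are stratified per class with largest-remainder apportionment of the
70/10/20 fractions, deterministic given the seed. Variance-based CpG
selection (default k = 200 000) must be computed on the training split
only; validation/test arrays are subset to the training-selected CpGs.
Model selection keeps the epoch with the best validation loss (validation
accuracy selectable in config). The randomized hyperparameter search
samples choices uniformly, learning rates log-uniformly, and layer widths
conditionally on a sampled depth; trials that diverge are recorded with
infinite loss instead of aborting the scan.

## Interpretation and networks

- **Routing networks.** Averaging per-sample couplings preserves
  row-stochasticity by linearity. The bipartite→unipartite projection
  correlates, for each gene, its routing profile flattened across
  samples × classes (the per-sample variant is primary; the coarser
  averaged-profile variant sits behind a flag, since either reading of
  "projecting across samples" is defensible). Louvain modularity runs on
  negative-clipped weights — modularity requires nonnegative edges — while
  the signed matrix is preserved for reporting.
- **kNN modules** use a union-of-neighbors unweighted graph, k = 15 by
  default (no principled value is forced by the data; 15 is the common
  embedding-graph default).
- **Clustering metrics.** Ward/Euclidean agglomerative clustering (default
  14 clusters for tumor-subtype embeddings); V-measure and silhouette with
  percentile bootstrap CIs (1000 resamples, seeded).
- **Context enrichment.** The top-k CpGs (default 1000) by signed or
  absolute weight against a boolean context; odds ratio ad/bc with the
  Haldane–Anscombe 0.5 correction when any cell is zero (flagged), p from
  the two-sided Fisher exact test.
- **Beta threshold.** Gaussian KDE (Scott bandwidth — no strong reason to
  prefer another rule on [0,1]-supported data at these sample sizes) on a
  512-point grid; the threshold is the lowest-density local minimum in
  [0.2, 0.8] that has a density peak at least twice its height on each
  side. The prominence condition rejects spurious wiggles in a decaying
  unimodal tail; without any qualifying valley the fallback is 0.5.
- **Comethylation.** Unsigned power adjacency |cor|^β with β = 6 by default
  (the scale-free-fit picker chooses the smallest β with R² ≥ 0.8 when
  wanted); TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)
  with unit diagonal; modules by average-linkage clustering of 1−TOM cut by
  count or height — a fixed cut rather than a dynamic tree cut, trading the
  adaptive heuristic for determinism. Singleton clusters are labeled
  unassigned (−1). Eigengenes are the first PC of the column-standardized
  submatrix, sign-oriented positively against the module mean profile.
- **Moderated test.** Two-group least-squares effects with residual df
  n−2; the prior (d₀, s₀²) is fit by the method of moments on log residual
  variances (trigamma inversion by Newton iteration), posterior variance
  (d₀s₀² + d·s²)/(d₀ + d), t with d₀ + d df, BH adjustment. The
  implementation is cross-checked in the tests against an independent
  reference fit of the same model, and `prior=(0, ·)` recovers the ordinary
  equal-variance t-test exactly. Only the two-group design is implemented,
  matching per-subtype versus control contrasts; multi-group F-tests are
  out of scope.

## Problem sizes and determinism

The test suite and acceptance script run the full study conditions stated
above (600–3000 simulated samples, 200–500 CpGs); every stochastic routine
takes an explicit seed or `numpy` Generator, and the acceptance script
derives all of its seeds from the single `--seed` argument. Degenerate
inputs (empty maps, singleton modules, zero-variance profiles, ties) follow
the documented conventions rather than erroring where a sensible value
exists, and error messages name the offending cell, CpG, or class.

## Known limitations

- The capsule network's backward pass does not differentiate through the
  routing iterations; this is a standard simplification and training
  converges on all tested settings, but gradients are not exact for the
  full unrolled computation.
- Group-L1 shrinkage is subgradient-based, so exact zeros are only
  approached; selection uses the documented norm threshold.
- The simulator's independence assumptions (see above) mean results on real
  arrays with batch structure may differ; no batch correction is included.
- Scalability targets desk-scale problems (hundreds of capsules); the
  per-(child, parent) transform tensor grows as capsules × classes and is
  the binding constraint for very large capsule sets — the sparse pathway
  network is the intended tool there.
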