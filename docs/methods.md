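# Methods

This note records the models implemented in `aesig`, the conventions and
defaults chosen where the design was genuinely open, and what the
synthetic cohort does and does not emulate.

## AE-signature model

The report count matrix `X` (p AEs × n drugs) is modeled as approximately
Poisson around a low-rank nonnegative product `WH`. The factorization
minimizes the generalized Kullback–Leibler divergence `D(X‖WH)` by
Lee–Seung multiplicative updates; KL is the default because the entries
are report counts (a Frobenius option exists behind the `loss` flag).
Each run starts from seeded uniform `(0,1]` matrices scaled by
`√(mean(X)/k)` so `WH` starts at the magnitude of `X`; 50 restarts are
used by default and the best final objective wins. After fitting, `W` is
column-normalized (each signature a probability distribution over AEs)
with the inverse scale folded into `H`, which leaves `WH` unchanged;
abundance fractions are `H` columns normalized to sum to one, computed
after the `W` normalization (the product is invariant to the order).
Multiplicative updates guarantee a monotonically non-increasing objective,
which the tests assert per iteration.

**Rank selection.** For each candidate k, repeated independently seeded
single-start factorizations produce argmax cluster labels; the consensus
matrix holds the fraction of runs in which each drug pair co-clusters, and
the cophenetic correlation between the average-linkage dendrogram of
`1 − consensus` and the consensus distances scores stability. The selected
k maximizes cophenetic correlation, ties resolved toward the smaller k.
The default is 20 consensus runs: with only 10, a coarse k (e.g. 2 on
four-block data) occasionally appears perfectly stable by chance and the
smallest-k tie-break then picks it; 20 runs resolve such spurious ties
while staying cheap at these matrix sizes.

## Similarity construction

One metric per modality, each mapping into [0, 1]: cosine similarity of
relative AE-frequency vectors; Tanimoto on binary fingerprints (all-zero
fingerprint pairs are defined as similarity 0 rather than NaN to keep
matrices total); Spearman correlation of expression columns shifted by
`(ρ+1)/2`. The metrics are deliberately pluggable — they are standard
choices per modality, not a modeling claim.

## MDS imputation

Similarities convert to squared dissimilarities as `d² = 2(1 − s)`, which
is exact for cosine similarity of unit vectors (`‖u−v‖² = 2 − 2cos`).
Double-centering a PSD *similarity* kernel directly would produce a
negative-semidefinite operand, so the centered operand here is always the
squared-dissimilarity form; this keeps the retained eigenvalues
nonnegative, as the embedding assumes. Classical MDS then
eigendecomposes `C = −½·H·d²·H`; eigenpairs with `λ > 1e-8·λ₁` are kept,
capped at `min(n−1, 10)`. The threshold acts as a numerical-rank detector:
an exactly low-rank network keeps exactly its rank (so the embedding
round-trips distances to machine precision), while noisy networks are
truncated at ten dimensions to keep the downstream regression well-posed
with a few tens of shared drugs. Negative eigenvalues (non-Euclidean
input) are discarded and logged.

The cross-network map is ordinary least squares of target coordinates on
anchor coordinates over the shared drugs, *with an intercept*: the two
embeddings are centered over different drug sets, and without the
intercept that centering mismatch biases every prediction. Predicted
coordinates convert back through `s = clip(1 − d²/2, 0, 1)`. Observed
target entries are never recomputed — they pass through bitwise.

## Network fusion

The completed networks are fused by cross-diffusion: full kernel
`P_ij = s_ij / 2Σs_i·` (diagonal ½), sparse kernel over each drug's K
most-similar neighbors (ties broken by identifier so the kernel is
deterministic), and `t` rounds of `P_v ← S_v · mean_{w≠v}(P_w) · S_vᵀ`
with symmetrization after every update. Defaults `K = max(3, n/10)`,
`t = 20`; similarities enter the kernels directly since they already live
in [0, 1] (no scaled-exponential re-kernelization). The diffusion limit
concentrates mass on drugs with large total affinity, which distorts
nearest-neighbor queries, so the averaged matrix is symmetrically
degree-normalized (`M_ij / √(m_i m_j)`), rescaled to [0, 1], and given a
unit diagonal before being returned. Fusion is order-invariant in the
input networks and permutation-equivariant in drugs.

## Label propagation

Drugs without observed labels receive the cluster with the largest total
fused similarity among their five most-similar observed-labeled drugs
(ties → larger total weight, then smaller cluster index). Observed labels
are immutable. The vote, its K, and the supporting neighbors are recorded
in the run manifest; the five-neighbor default mirrors the neighbor count
used for reporting nearest neighbors.

## SOC enrichment

For a category with m member AEs and signature v, the one-sided
(greater) Mann–Whitney test compares the m probabilities `W_iv` against
the same m AEs' probabilities pooled over the other k−1 signatures —
pooling the *same* AEs, not all AEs, matching the statistic's index
structure. The exact null is used when the pooled sample has at most 12
tie-free values; otherwise the tie-corrected normal approximation with
continuity correction. The effect size divides the mean difference by the
sample (n−1) standard deviation of the pooled vector; a zero pooled sd
yields a signed-infinity sentinel with a warning. Raw p-values drive the
default significance flag (a Benjamini–Hochberg column is emitted for
reference), matching how such category scans are conventionally reported.

## Tissue proximity

Tissue-specificity scores are `Z_tg = (Ē_tg − Ē_g)/S_g` with the mean and
sd taken across per-tissue means (tissue granularity, not sample-weighted);
constant genes score zero. The top `n_top` genes per tissue (default 200;
boundary ties broken by identifier) form the tissue module. Drug–tissue
distance is the size-normalized sum of closest-pair BFS distances between
the target module and the tissue module; unreachable pairs contribute
`diameter + 1` so disconnection is penalized without shrinking the
denominator. Significance is the fraction of `n_perm = 100` size-matched
uniform random draws (from all network genes; degree-matched sampling is
available behind a flag) whose distance falls *strictly* below the
observed one — zero is therefore attainable and is reported as such, with
the `-log10` display mapping 0 to `log10(n_perm) + 1`.

## Sparse discriminant genes

Cluster contrasts are coded `y = −n/n₁` vs `+n/n₂` and solved as
`argmin n⁻¹Σ(y − β₀ − xᵀβ)² + λ‖β‖₁` by cyclic coordinate descent with an
active-set sweep strategy, along a 100-point geometric λ grid from
`λ_max = 2·max_g|⟨x_g, y−ȳ⟩|/n` (the smallest penalty with an all-zero
solution under this objective) down to `0.01·λ_max`. Genes are
standardized internally and coefficients reported on the original scale;
constant genes are dropped with a warning. Because the cohorts are far too
small for cross-validation, the discriminant set is read at the smallest
grid λ; alternative rules sit behind a flag. Solutions satisfy the
optimality (KKT) conditions to below 1e-5 along the path, and the
orthonormal-design solution matches closed-form soft-thresholding.

**Known limitation.** When many discriminant genes share one mean-shift
signal, the signal subspace is rank one: after a handful of correlated
genes enter the model the residual signal is exhausted, and the remaining
planted genes compete as noise. At 8-vs-8 drugs with 10 planted genes the
selected set therefore plateaus around 6 planted genes at *any* λ — an
intrinsic property of l1 selection at this sample size (an independent R
glmnet fit selects the same genes), not a solver artifact. Discriminant
sets from small cohorts should be read as representatives of correlated
signal groups, not exhaustive lists.

## Synthetic cohort

The generators produce every pipeline input with planted ground truth:

* **Counts.** `W_true` gives each signature a disjoint high-probability AE
  block (85% of its mass) plus a common background, so signatures are
  identifiable (pairwise cosine < 0.3); `H_true` is column-stochastic with
  a 0.75 dominant loading; counts are Poisson with per-drug mean totals.
  In the default fixture, half the drugs get ~600 reports and half ~8, so
  the report-count filter (default 20, emulating a minimum-feedback rule)
  naturally splits the roster into NMF-labeled and propagation-only drugs.
* **Similarity sources.** Drugs get latent coordinates in the positive
  cone — around `3·1` when unstructured, or around well-separated
  positive-orthant axis directions (norm 4, within-cluster sd 0.3) when a
  cluster assignment is supplied, giving within/between cosines of ~0.99
  vs ~0–0.7. Each source applies its own random orthogonal map plus
  coordinate noise, unit-normalizes, and takes cosines clipped to [0, 1].
  Orthogonal (rather than general affine) distortions keep the
  anchor-to-target coordinate relation exactly linear, so noise-free
  imputation is exact and the recovery tests are well-posed; the positive
  cone keeps the clip inactive for the same reason. Source 1 (the AE-like
  source) always has full coverage and anchors imputation.
* **Expression.** N(0,1) background with disjoint per-cluster-pair gene
  sets shifted by ±effect/2 (planted mean gap = effect size).
* **Tissue world.** Giant component of a seeded Erdős–Rényi graph (mean
  degree 6); each tissue owns a disjoint 20-gene block elevated by 3
  units. Tissue-associated drugs draw ~80% of their targets from their
  tissue's block and the rest from first neighbors — a deliberately strong
  association so the permutation test's power is not the quantity under
  test; null drugs draw targets uniformly.
* **SOC map.** Each signature's AE block maps to one distinct category;
  remaining AEs are assigned uniformly.

What the cohort does *not* emulate: report-level duplication and
demographic structure of real surveillance data, ontology hierarchies
beyond a single SOC level, realistic fingerprint bit correlations, or
scale-free interactome topology. Passing recovery tests therefore shows
the pipeline recovers the structure it assumes, not that real data
satisfies those assumptions.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by choice: cohorts of
15–100 drugs, 80–150 AE terms, 200–300 genes, 100 permutations, 500
calibration replicates, 10-seed repetition for stochastic claims. One
integer seed determines every stochastic stage (generators, NMF restarts,
permutations, consensus runs) through hierarchical seed sequences, and
rerunning the pipeline with the same seed reproduces every output file
checksum-identically.
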