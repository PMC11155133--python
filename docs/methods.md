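# Methods

## Problem and model

Spatial transcriptomics assays measure an expression profile and a 2-D
coordinate for every spot (or cell) in a tissue section. The package learns a
joint low-dimensional embedding of both modalities and segments the tissue
into spatially coherent expression domains, without supervision.

The model couples two encoders through a single reconstruction objective:

- **Expression branch.** A two-layer affine encoder with Elu activations maps
  the preprocessed expression matrix `X ∈ R^{N×F}` to `H_f ∈ R^{N×D_f}`
  (hidden 100, `D_f = 20`). Affine layers carry biases.
- **Spatial branch.** A hypergraph is built from the coordinates: one
  hyperedge per spot, equal to the spot plus its `k = 20` nearest Euclidean
  neighbors. This per-spot-star rule simultaneously realizes a
  kNN-derived hypergraph and self-inclusion (the incidence diagonal is 1),
  which keeps every vertex degree positive. The normalized adjacency
  `A_hp = D_v^{-1/2} P W_e D_e^{-1} P^T D_v^{-1/2}` is symmetric PSD with
  eigenvalues in [0, 1]; hyperedge weights are fixed at identity (exposed in
  the API but untuned). Two independent two-layer hypergraph convolutions
  `A_hp·ReLU(A_hp H_f W_1)W_2` (hidden 32, output `D_g = 8`, no biases) act
  as the mean and log-std heads of a diagonal Gaussian over the spatial
  embedding `H_g`. Training draws `H_g = μ + σ⊙ε` by reparameterization; the
  final embedding uses the mean. No KL prior is applied — the variational
  sampling acts purely as stochastic regularization.
- **Decoder.** One affine layer reconstructs `X′` from `H = [H_f, H_g]`
  (`D = 28`).

### Objective

`L = Loss_rec + λ·Loss_clu + γ·Loss_spa` with defaults `λ = 0.1`, `γ = 1`.

- `Loss_rec` — mean squared error over all `N·F` entries of `X − X′`.
- `Loss_clu` — deep-embedded clustering: Student-t (1 d.o.f.) soft assignment
  `q_ik ∝ (1 + ‖h_i − μ_k‖²)^{-1}` of spots to `K = 10` centroids, sharpened
  target `t_ik ∝ q_ik²/Σ_i q_ik` (row-normalized), loss `KL(T‖Q)`. The target
  `T` is recomputed once per epoch from the current `Q` and treated as a
  constant within the epoch. Centroids are free parameters updated by the
  optimizer, initialized by k-means (10 restarts, best inertia) on the
  mean-mode joint embedding.
- `Loss_spa` — with `D^(s)` and `D^(h)` the pairwise Euclidean distance
  matrices of coordinates and embeddings, both min-max normalized to [0, 1]
  (the diagonal zeros make this division by the maximum; an all-zero-range
  matrix normalizes to zeros), the loss is the mean over all `N²` ordered
  pairs of `D^(s)_ij (1 − D^(h)_ij)`. Spatially distant pairs are thereby
  pushed apart in embedding space.

### Training schedule

Full batch throughout; Adam with learning rate 0.01. Stage 1 ("pretraining",
200 epochs) optimizes `Loss_rec + γ·Loss_spa` — the clustering term is the
only exclusion. Stage 2 (200 epochs) optimizes the full objective. No early
stopping and no learning-rate schedule. Every stochastic stage (weight
initialization, reparameterization noise, k-means, PCA, Leiden) consumes a
seed derived deterministically from the master seed plus the stage name, so a
run is exactly reproducible from its config.

## Numerical choices

- **KL scale.** `Loss_clu` as a raw double sum grows linearly with N (≈170 at
  N = 800 versus a reconstruction MSE below 1), so a fixed `λ` would mean
  radically different effective weights across dataset sizes, and in practice
  the summed term collapses the embedding onto the K centroids — the
  embedding fragments into disconnected clumps and community detection can no
  longer reach the requested domain count. The training objective therefore
  uses the per-spot mean KL (the "batchmean" convention standard in DEC
  implementations). The public `dec_loss` function reports the plain double
  sum.
- **Spatial-loss cost.** `Loss_spa` is O(N²); it is evaluated dense up to
  8 000 spots (row-chunked in the inference-side implementation) and beyond
  that by an unbiased Monte-Carlo estimate over 2 048 uniformly sampled
  ordered pairs per step, with normalization maxima still computed exactly.
- **Stability.** The log-std head is clamped to [−10, 10] before
  exponentiation; pairwise embedding distances add a 1e-30 floor inside the
  square root so the gradient is defined at the zero diagonal; `q_ik` and
  `t_ik` denominators are floored at 1e-12. Non-finite losses abort with the
  offending epoch.
- **Gradients.** All gradients come from a reverse-mode autodiff core over
  float64 numpy arrays written for exactly this model (matmuls, Elu/ReLU,
  reductions, sparse-dense products, concatenation, a global max). Analytic
  gradients of the complete objective match central differences to better
  than 1e-4 relative error (tested); clamp and max use sub-gradients (zero
  outside the interval; gradient routed to the first argmax).
- **Ties and determinism.** kNN distance ties break by ascending spot index;
  PCA uses the full SVD solver with the sign convention that each component's
  largest-magnitude loading is positive; Leiden is seeded and the resolution
  search (geometric bisection on [1e-4, 10], ≤ 40 evaluations) prefers the
  smallest resolution that achieves the target community count, returning the
  closest count with a flag when the target is unattainable.

## Preprocessing

Fixed order, each step recorded in a provenance list (re-application
raises): genes expressed in fewer than 5 spots are removed; each spot is
divided by its total so counts sum to 1 (the literal target, not the common
1e4); `log(1 + x)`; per-gene scaling to zero mean and unit (population)
variance with zero-variance genes set to all-zeros rather than dropped,
keeping column indices stable; no post-scaling clipping. PCA to 200
components follows, skipped entirely when the gene count is already ≤ 200
(so low-plex panels such as 33-gene osmFISH data pass through unchanged).
Spots with zero total counts are rejected with an explicit error rather than
silently dropped. Marker-gene t-tests run on the log-normalized matrix
*before* per-gene scaling, which would otherwise destroy effect
directionality.

## Evaluation metrics

ARI (pair-counting, via the contingency table) and NMI (mutual information
normalized by the geometric mean of the entropies; 1 when both partitions are
the single trivial cluster) score agreement with ground truth. The label
Moran's index needs no truth: on the directed spatial kNN graph (k = 20) it
is `Σ_ij A_ij B_ij / Σ_ij A_ij` with `B_ij = 1[y_i = y_j]` — the printed
two-factor form `(N/ΣΣA)·(ΣΣAB/N)` cancels its N algebraically, and the
implementation is property-tested against that literal expression. Both
orientations of each directed edge are counted, exactly as the double sum
prescribes.

## Synthetic data generator

The generator emulates a small layered tissue: spots uniform in the unit
square; domains as K horizontal strips (cortex-layer-like; the strip index is
an exact function of the y coordinate) or seeded Voronoi cells; background
expression from a Gaussian (mean 10, SD 2, clipped at 0 — clipping is a
~5-sigma event) or negative-binomial (mean 5, dispersion 2) model; each
domain's marker genes get an in-domain mean shift expressed in background SD
units. Defaults — 800 spots, 200 genes, 4 strips, 5 markers per domain,
+3 SD, Gaussian — are the study conditions for all end-to-end checks and keep
a full double training run around half a minute on one CPU.

What it does *not* emulate: platform artifacts (lateral diffusion, spot
swapping, segmentation errors), library-size variation across spots,
gene–gene correlation beyond the domain structure, curved or nested domain
geometries, and dropout patterns of real counts. Passing end-to-end tests
therefore demonstrates the machinery recovers planted structure under clean
conditions, not performance on real tissue.

A geometric note on spatial coherence: for uniform spots the expected
fraction of kNN edges crossing a strip boundary is ≈ `6r·0.212` with
`r = sqrt(k/(πN))`, so the ground-truth label Moran's index at k = 20 is
≈ 0.85 at N = 500 and ≈ 0.88 at N = 800, approaching 1 only as density grows
(≈ 0.93 at N = 2000). Predicted segmentations can score slightly above the
ground truth because the learned boundaries are smoother than the sampled
strip edges.

## Design decisions taken where the design was open

- Hyperedges are per-spot stars rather than mutualized kNN sets (the standard
  kNN-hypergraph recipe; also yields constant hyperedge degree k + 1).
- The two HGCN heads share no weights.
- Pretraining runs the full joint forward pass (including the sampled spatial
  branch) with the clustering term excluded — nothing else.
- The γ weight applies once, in the combined objective.
- DEC uses `--assigner {leiden,dec}`: Leiden on the joint embedding is the
  default final segmentation; the DEC argmax assignment is exposed as an
  alternative.
- CPU is the default device; the implementation is pure numpy/scipy and has
  no accelerator path.

## Limitations

- Full-batch training with dense N² spatial distances bounds practical size
  to tens of thousands of spots; beyond 8 000 the spatial term switches to
  pair sampling but the forward pass itself remains full-batch.
- The resolution search cannot force a community count the kNN graph
  topology cannot express (e.g. fewer communities than connected components);
  such runs are flagged rather than failed.
- Histology images and 3-D coordinates are out of scope; coordinates are
  assumed 2-D Euclidean.
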