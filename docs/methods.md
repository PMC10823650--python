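# Methods

## Problem and data model

The observable is a binary association matrix `A` (m circRNAs × n diseases)
assembled from a TSV edge list; `A[i,j]=1` means an experimentally supported
link.  Four auxiliary edge lists (circRNA–miRNA, miRNA–disease, circRNA–gene,
disease–gene) are consumed as given — the package never predicts side edges —
and are aligned to the corresponding side of `A`; primaries absent from a side
table get all-zero rows, and side-table entries whose primary is not in `A`
are dropped with a warning.  Identifiers are opaque case-sensitive strings;
any name unification must happen upstream.

## Similarity construction

Both transfer principles the model relies on — "diseases associated with a
circRNA's miRNA partners are candidate diseases for that circRNA", and the
same for disease-causing genes — are encoded as per-side similarity graphs:

* GIP kernel over association profiles: `K(i,j) = exp(−γ‖p_i−p_j‖²)` with
  `γ = 1/mean‖p‖²`.  Rows of `A` for circRNAs, columns for diseases.
* Jaccard similarity of auxiliary-neighbor sets per side network.
* Fusion `S = γ_f·GIP + (1−γ_f)·mean(side Jaccards)` with `γ_f = 0.5`
  (balanced by default; `fusion.gamma` in config).  With no side tables the
  GIP kernel is used alone.
* kNN sparsification (`graph.k_neighbors = 10`, keeping convolution local on
  graphs of hundreds of nodes), symmetrisation by elementwise max, self-loops,
  and symmetric normalisation `D^{-1/2}(S+I)D^{-1/2}` whose spectral radius
  is ≤ 1, keeping repeated convolution non-expansive.

During any evaluation, the GIP input is the training matrix with held-out
positives zeroed, so similarity never sees test labels.

## Embedding

Alternating ridge factorisation minimises
`½‖A−CDᵀ‖²_F + λ(‖C‖²_F+‖D‖²_F)`; each half-step is an exact ridge solve
(`C ← AD(DᵀD+2λI)^{-1}` and symmetrically), so the objective is monotonically
non-increasing — the per-sweep objective trace is recorded and asserted in
tests.  Defaults: `k = 64` capped at `min(m,n)−1`, `λ = 0.01`, `tol = 1e−5`,
uniform `(0, 1/√k)` seeded initialisation.  The regulariser is applied
symmetrically to both factors; no nonnegativity constraint is imposed.

A fixed, seeded one-layer 1-D convolution (8 channels, width 3, ReLU, same
padding) expands each entity's latent vector into `8k` features.  The kernels
are not trained: the feature map is a deterministic random projection whose
refinement happens downstream in the encoder that consumes it.  This keeps
the embedding stage closed-form and reproducible.

## Dual graph autoencoders and variational EM

Per side `s ∈ {c, d}` the node features are `x_s = [association profile ‖
conv features]`.

**GNNq** (inference): graph-convolution layer (hidden 64, ReLU) followed by
two linear graph-convolution heads producing `μ` and `log σ`;
reparameterised sample `z = μ + σ⊙ε`; a linear decoder maps `z` back to the
feature space.  Because the feature vector begins with the node's
association profile, the first block of the reconstruction is the candidate
score matrix — the score head is that decoder slice, anchored to observed
labels through the reconstruction loss.  (A separate score head trained only
through the co-training penalty receives no label gradient and does not
rank; this is why the decoder-slice realisation was chosen.)
Loss per side: `L_q = ½‖x−x′‖²_F + KL`, with
`KL = −Σ ½(1+2log σ−μ²−σ²)`.

**GNNp** (propagation): two graph-convolution layers (ReLU then sigmoid)
mapping pseudo-labels to propagated matrices `F_c (m×n)` and `F_d (n×m)`.
Loss per side: positive-cell cross-entropy `−Σ Y log F` plus Laplacian
smoothness `tr(FᵀLF)/|E|` over the dense fused similarity (unnormalised
Laplacian, per-edge normalised so the penalty is comparable across graph
densities).

**Coupling and schedule.**  Each epoch runs one Adam step (lr 0.001, gradient
norm clipped at 5) on
`L_q = αL_qc + (1−α)L_qd + βL_c`, where `L_c = ‖S_c−S_dᵀ‖²_F/(mn)` and
`β = e/E` at epoch `e` of `E` (the co-training constraint is trusted more as
the representations mature), then recomputes deterministic (mean-latent)
scores, forms soft pseudo-labels `Y_s = max(clip(S_s,0,1), A_train)`, and
takes one Adam step on `L_p = αL_pc + (1−α)L_pd`.  `α = 0.8` weights the
circRNA space more heavily.  Final output: `F = αF_c + (1−α)F_dᵀ`.

The positive-only cross-entropy admits a degenerate attractor (all
predictions → 1 drives the loss to 0 regardless of labels); the sigmoid
output never reaches it exactly and the finite default schedule (500 epochs)
stops well inside the informative regime — consistent with the observation
that very long schedules degrade ranking.  Divergence (non-finite loss)
aborts with a diagnostic rather than returning garbage.

All randomness (initialisation, reparameterisation noise) flows from one
integer seed; two runs with identical config and seed produce byte-identical
score files.  Training is permutation-equivariant only in distribution:
weight initialisation and noise are drawn positionally, so relabelling rows
changes individual runs while leaving the deterministic algebra (kernels,
fusion, normalisation, fusion of `F_c`/`F_d`) exactly equivariant — the test
suite checks equivariance at the level where it is exact and determinism at
the pipeline level.

The networks are implemented on a minimal reverse-mode autodiff core
(`circlink.autodiff`, ~200 lines: matmul, broadcast arithmetic, relu,
sigmoid, exp, log, slicing, sums) with a hand-written Adam optimiser; its
gradients are validated against central finite differences in the test
suite.  At these problem sizes (hundreds of nodes) dense numpy is faster
than any framework overhead would allow.

## Evaluation

Fivefold cross-validation partitions positive *cells* uniformly at random
(fold sizes differ by ≤1).  Per fold, test positives are zeroed before any
other computation and the candidate set is the test positives plus all
unobserved cells — no negative sampling, since the matrices are small enough
to rank exhaustively; ties receive half credit in AUROC.  AUROC and AUPR are
computed by scikit-learn and cross-checked in tests against brute-force
pair-counting and threshold-enumeration oracles.

A caveat on comparability: the candidate set defines the metric.  When an
association table is round-tripped through TSV, entities with no known
positives vanish from the matrix, removing their (easy-to-rank) cells from
the candidate set; AUROC on the reduced matrix is therefore lower than on
the full grid for the same model.  Numbers should only be compared at a
fixed candidate set.

## Synthetic benchmark generator

The generator emulates the statistical shape of curated benchmarks, not
their biology: half-normal nonnegative factors `U (m×r)`, `V (n×r)` scaled
by `factor_scale`; `P(A_ij=1) = logistic(c + u_i·v_j)` with `c` calibrated
by bisection to hit the target density; side-network membership interpolates
between a constant-rate null (`side_strength = 0`, independent of `A`) and a
latent-aligned logistic model (`side_strength = 1`), with the intercept
calibrated so total side density is constant in the strength.  A fraction of
realised positives (default 20%) is recorded as held out and zeroed in the
returned training matrix.

Defaults (m=200, n=50, rank 3, density 0.05 ≈ the ~1% sparsity regime of
real benchmarks scaled to a denser, smaller grid; side density 0.05;
`factor_scale = 2`) make the planted structure strongly identifiable: the
skyline predictor `UVᵀ` attains masked-recovery AUROC ≈ 0.99, so shortfalls
measured on the fixture are attributable to the model, not to irreducible
noise.  What the generator does **not** emulate: disease ontology structure,
literature curation bias, circRNA naming, or heavy-tailed degree
distributions — passing on the fixture shows the machinery recovers planted
low-rank-plus-side-information structure, not that real-world AUROC will
match.

## Problem sizes and runtimes

The shipped test suite trains on a 60×20 fixture (40 epochs) for pipeline
contracts and on the 200×50 fixture (500 epochs, 5 seeds × 3 side strengths)
for recovery and monotonicity properties; the full suite runs in ~1.5 min on
one CPU, and `scripts/acceptance.py` in ~2 min.  These sizes were chosen so
the planted-structure conclusions are stable across seeds while iteration
stays interactive.

## Known limitations

* Cold start: an entity absent from the association table cannot be scored
  (no row/column), even if present in side networks.
* The co-training and manifold losses are this package's concrete
  realisations of cross-space consistency and label smoothness; each sits
  behind a single function so alternatives can be swapped.
* Hyperparameters beyond α, learning rate and the β schedule were fixed at
  standard values, not searched; `cv` plus config overrides is the supported
  way to tune on a new dataset.
* Scores are not calibrated probabilities; only the ranking is meaningful.
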