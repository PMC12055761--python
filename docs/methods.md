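# Methods

This note documents the model, the choices behind every tunable parameter,
what the synthetic benchmarks do and do not show, and the limitations we
found while validating the pipeline.

## Model and assumptions

The data is a binary bipartite adjacency `A ∈ {0,1}^{U×V}` over U
metabolites and V diseases. The working assumptions are:

* observed associations are positive examples; unobserved pairs are a
  mixture of true negatives and undiscovered positives (candidate set);
* the association structure is approximately low-rank — a metabolite's
  disease profile is a non-negative combination of a few latent metabolic
  programs — which is what makes NMF features informative;
* curation noise exists in both directions (spurious and missing edges),
  which motivates the Bernoulli edge masking: an encoder that never sees a
  fixed edge set cannot memorize spurious associations.

### Stage 1 — regularized NMF

Objective `‖W⊙(A−MD)‖²_F + μ₁‖M‖²_F + μ₂‖D‖²_F`, minimized by alternating
multiplicative updates (M first; the D update uses the fresh M). The weight
matrix `W` has two modes: all-ones (default — every cell, including zeros,
constrains the fit) and observed-only. Multiplicative updates preserve
non-negativity and never revive an entry that reaches exactly zero; factors
are therefore initialized strictly positive, uniform on (0, 1].

* `K` (latent dimension, default 90): must satisfy the compression
  constraints `K < min(U, V)` and `K < UV/(U+V)`. 90 suits a
  curated-database-scale network (thousands × hundreds). On synthetic
  benchmarks the constraint binds: for a 300×60 network `K < 50`, and we
  use `K ≈ min(30, min(U,V)/2)` — the same ~0.4·min(U,V) proportion the
  default represents at database scale.
* `μ₁ = μ₂ = 0.01`: light Tikhonov damping; enough to keep factor norms
  bounded without visibly biasing the fit.
* `max_iterations` 500, `rel_tolerance` 1e-6 on the relative objective
  decrease; with `rel_tolerance=0` the iteration count alone governs.
* `eps_div` 1e-12 guards denominators; it only matters for exactly-zero
  rows/columns (e.g. a held-out disease), where the regularized minimizer
  is genuinely zero.

A caution that matters for interpreting reconstruction numbers: a *binary*
matrix obtained by thresholding a rank-r score matrix is itself close to
full rank. On a clean planted 60×30 rank-3 network the best possible rank-5
approximation (SVD) already has relative Frobenius error 0.31, and the
multiplicative updates converge within ~9% of that bound. Low reconstruction
error on the 0/1 matrix is therefore not an achievable target for any
compressive factorization; what the features must do is *order* pairs well,
which the end-to-end benchmarks measure.

### Stage 2 — masked graph autoencoder

Per epoch: draw `E_mask ~ Bernoulli(τ)` over observed edges, encode on
`E_reserved` only, score **all** observed edges (masked included) plus an
equal number of freshly resampled unobserved pairs with BCE, regress all
node degrees of the full observed graph with MSE, and take one full-graph
Adam step on `L_edge + l·L_degree`.

* Encoder: GIN with trainable per-layer blend `ε` (init 0) and a
  Linear–ReLU–Linear MLP per layer; dims [64, 128]. GCN
  (symmetric-normalized bipartite adjacency with self-loops) and
  single-head GAT are selectable. 2–4 layers supported.
* Edge decoder: pair combiner (Hadamard default; inner / sum / concat) +
  MLP [128, 64] + sigmoid. The pure inner-product mode squashes
  `w·⟨h_m, h_d⟩ + b` directly. The Hadamard default keeps the
  inner-product structure termwise while giving the MLP a vector input.
* Degree decoder: MLP [128, 64], linear output. It regresses degrees of the
  full observed graph, not the masked one — its role is to anchor true
  neighborhood density.
* τ = 0.4, l = 0.6, learning rate 0.001 (Adam), negatives 1:1 resampled per
  epoch, default 300 epochs (the loss plateaus well before this on all
  benchmarks; more epochs measurably change nothing).
* BCE scores are clipped to [1e-7, 1−1e-7]; a non-finite loss aborts with
  the epoch index.
* Ablation switches: `use_masking=False` (τ→0), `use_degree_decoder=False`
  (l→0), `use_nmf_features=False` (seeded uniform features of the same
  shape — the weakest informative baseline, since no replacement is
  canonical).

Inference embeddings are computed once on the complete observed graph
(no mask). We evaluated Monte-Carlo averaging over masked graphs instead —
it is slightly better on held-out edges (+0.01 AUC) but complicates the
inference contract and was not adopted.

All parameters are Glorot-initialized from one seed; a single global seed
derives independent per-stage seeds (NMF init, masking, negative sampling,
parameter init, fold split) through a documented counter scheme
(`mdgae.gae.derive_seed`), so any stage can be reproduced in isolation.

The gradients come from a minimal reverse-mode autodiff core
(`mdgae.autodiff`) written for this package and checked against central
finite differences in the test suite.

### Stage 3 — evaluation and ranking

Cross-validation splits *edges*, not nodes; per fold the held-out positives
are removed from the training adjacency and the NMF features are recomputed
on the reduced network, so held-out edges cannot leak through features.
Fold negatives are fixed, sampled 1:1 from never-observed pairs, disjoint
across folds. Threshold 0.5 for the confusion-matrix metrics; AUPR is the
step-wise (non-interpolated) area; zero-denominator metrics report 0 with a
warning flag. Ranked outputs break score ties lexicographically by
identifier so they are reproducible.

## The synthetic benchmark

`generate_planted_network` samples factors i.i.d. uniform [0,1), keeps the
top `⌊U·V·density⌋` scores as edges (quantile thresholding → exact edge
count, deterministic fixtures), then flips `round(ρ·U·V)` uniformly chosen
cells. It emulates: low-rank association structure, sparsity, and symmetric
curation noise. It does **not** emulate: the heavy-tailed degree
distribution of real curated data (most real metabolites have 1–2
associations), identifier semantics, or any biochemical similarity
structure. Passing benchmarks therefore demonstrates that the machinery
recovers planted low-rank structure under noise — not that the specific
biological predictions of any real-data study transfer.

Benchmark scales were chosen to exercise the method at desk scale: 300×60
(rank 5, density 0.05, ρ = 0.02) for end-to-end CV, 150×40 (ρ = 0.1) for
the masking ablation, 100×25 for hold-out ranking.

## Findings and limitations

* **Noise bounds attainable CV scores.** With ρ = 0.02 on a 300×60 network,
  ~28% of observed edges are uniform random flips; held-out flipped
  positives are statistically identical to sampled negatives, so even an
  oracle scorer is capped near AUC 0.86 under this protocol. The pipeline
  reaches mean AUC ≈ 0.83 / AUPR ≈ 0.87–0.88, and beats gradient-boosted
  trees on the same NMF pair features and pure low-rank reconstructions
  under the identical protocol. On held-out *true* edges alone it reaches
  AUC ≈ 0.93.
* **Masking earns its keep under noise.** At ρ = 0.1 the masked model's
  held-out AUPR exceeds the unmasked variant's by ~0.15 (0.73 vs 0.57 over
  ten seeds) — the central robustness claim, reproduced qualitatively.
* **Cold-start ranking is a genuine failure mode.** In the
  leave-disease-out protocol the held-out disease has an all-zero feature
  vector (the exact regularized NMF minimizer for a zero column) and no
  edges, so its embedding is a small bias-generated vector lying in the
  region the decoder learned to call "non-association". Scores for its
  column then *anti*-correlate with metabolite degree (Spearman ≈ −1.0)
  while ground truth correlates positively, so true partners rank near the
  bottom — worse than random, and far worse than a trivial popularity
  ranking. Excluding the target column from negative sampling and switching
  to the inner-product decoder do not fix this: it is embedding geometry,
  not direct supervision. Any leakage-free dot-product-style scorer shares
  this limitation; case-study protocols on real data that report strong
  cold-start rankings should be scrutinized for feature leakage (e.g.
  features computed before edge removal). The protocol is implemented
  leakage-free here and its failure is reported honestly by the test suite.
* No mini-batching, early stopping, or hyperparameter search; training is
  full-graph and CPU-bound by design.
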