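# Methods

## Hypergraph representation

A cohort of |Q| subjects is modeled as a hypergraph A = (Q, E, M): incidence
matrix **B** ∈ {0,1}^{|Q|×|E|}, hyperedge weights m(e) ≥ 0 on the diagonal of
**M**. Weights are initialized to 1 and never trained; no principled update
rule exists for them in this design, so none is invented. Node degree
d(q) = Σₑ m(e)·B[q,e] (weighted), hyperedge degree d(e) = Σ_q B[q,e]
(unweighted). Duplicate hyperedges are retained as separate columns — the KNN
construction can produce them, and the additive degree formulas then count
multiplicity correctly. Validity requires every hyperedge nonempty and every
node covered (so D_q is invertible); violations raise at construction.

The normalized Laplacian L = I − D_q^{−1/2} B M D_e^{−1} Bᵀ D_q^{−1/2} is
symmetric PSD with spectrum in [0, 1+ε]; the implementation symmetrizes the
result to remove rounding skew and enforces symmetry/PSD at 1e−12 / 1e−8
tolerances in tests.

## Convolution operators

Spectral filtering with frequency response (1 − λ) in L's eigenbasis equals
multiplication by G_spec = I − L; this identity (the collapse of the
truncated-Chebyshev filter chain at first order with λ_max ≈ 2) is verified
against an explicit eigendecomposition oracle rather than exposed as a
runtime path. The spatial form G_spat = D_q^{−1} B M D_e^{−1} Bᵀ is
row-stochastic: node updates are convex combinations, constants are
preserved, and on connected hypergraphs repeated application contracts node
features toward a constant (oversmoothing). The explicit three-step message
passing (average into hyperedges by 1/d(e); scale by m(e) and sum at nodes;
divide by node degree) is implemented as loops and must agree with the
matrix form to 1e−8. One reconciliation: the per-node division uses the
*weighted* degree d(q), which equals the incident-hyperedge count |E(q)|
only for unit weights; the weighted form is normative so loop and matrix
forms agree for all weights.

Variance monotonicity under G^L is a property of the spatial operator (its
convexity bounds the feature range); the spectral operator contracts the
D^{1/2}-weighted variance instead, and its plain variance is not monotone.
Tests check the spatial form.

Operators are dense |Q|×|Q| matrices: target cohorts are tens to a few
thousand subjects, where dense algebra is simpler and fast; sparsity would be
an internal optimization, not a contract.

## KNN construction and multimodal fusion

Per modality, features are z-scored (population std; constant columns get a
unit divisor) with statistics from the training subjects only, then each
subject becomes the centroid of one hyperedge containing itself plus its Z
nearest neighbors (euclidean). Membership is centroid + Z, size Z+1, so
self-connection is guaranteed independently of Z; ties break by ascending
node index, making construction deterministic. Neighbor search uses a full
pairwise-distance matrix with a stable argsort — at these cohort sizes this
is both exact and fast, and it pins the tie-break order, which off-the-shelf
KNN indices do not.

Fusion concatenates per-node feature vectors along the feature axis (width
Σ_w d_w) and incidence matrices along the hyperedge axis (W·|Q| hyperedges)
over a shared, identically ordered node set. Fused node degrees are the sums
of per-modality degrees. Subjects missing a modality are not supported.

## Classifier and training

H = G^L X⁰ + diag(σ(R)) X⁰ with L = 2 propagation layers by default. R is a
learnable length-|Q| vector (the diagonal of the adaptive retention matrix)
initialized to zero, i.e. a neutral gate of σ(0) = 0.5; σ is the sigmoid.
The "static" ablation replaces σ(R) with the constant 0.5 and removes R from
the optimizer's parameter set. The transformation head is
FC(d→128) → ReLU → FC(128→C), with inverted dropout (rate 0.5) applied to
the input of each FC layer during training only; evaluation is
deterministic.

Training is transductive, full-batch ("epoch" = one gradient step): the
hypergraph and G^L X⁰ span all nodes, the loss is softmax cross-entropy on
train-mask nodes. Optimizer: Adam (β = 0.9/0.999, ε = 1e−8), lr 1e−3
multiplied by 0.7 every 200 epochs, 600 epochs, weight decay 5e−4 added to
every parameter's gradient. Gradients are closed-form (the model is a linear
propagation plus a 2-layer MLP and an elementwise gate), implemented in
NumPy; with a fixed seed the entire loss history is bit-reproducible. FC
weights use fan-in-scaled symmetric uniform initialization, biases zero.
Because the setting is transductive, R entries of unlabeled/test nodes
receive no label gradient and are regularized only by weight decay. A
consequence worth knowing: G^L X⁰ is precomputed once per fit, so training
cost is independent of L.

Divergence (non-finite loss) raises; a single-class training mask is
rejected up front.

## Evaluation protocol

Repeated stratified k-fold CV (default 10×10): for repeat r the fold
assignment comes from a stratified splitter seeded with base_seed + r, and
the cell (r, f) retrains from scratch with seed base_seed + r·folds + f.
Z-scoring statistics are recomputed from each training fold; the KNN
hypergraph spans all nodes (transductive). Because ablations, the Z grid and
the GCN baseline reuse the same enumeration, all comparisons are paired
fold-for-fold, and paired t-tests (closed form; identical vectors → p = 1,
zero-variance nonzero-mean differences → p = 0) quantify them. Accuracy and
macro-F1 (unweighted mean of per-class F1, classes absent from both truth
and prediction excluded) are the metrics; 3-class tasks read "F1" as
macro-F1.

The GCN baseline clique-expands the fused hypergraph (every pair inside a
hyperedge connected), builds D^{−1/2}(A+I)D^{−1/2}, and trains the identical
decoupled head under the same folds and seeds, so the only varying factor is
the propagation structure.

## Synthetic cohort generator

The generator emulates a small monitored elderly cohort: default 50
subjects, class proportions (0.4, 0.3, 0.3) over low/moderate/high risk,
three modalities of widths 8/6/4 (physiological, behavioral,
environmental). Per modality, class means sit at mutually orthogonal random
directions scaled so every pairwise mean distance is exactly
effect_size·noise_sd; features add isotropic Gaussian noise (sd = noise_sd,
default 1). Class counts follow the proportions exactly
(largest-remainder rounding, then a seeded shuffle), which keeps the
stratified 80/20 split (40/10 at n = 50) always constructible. The default
effect size 3.0 produces strongly but not perfectly separated classes.
Raw-input generators provide 1 Hz sinusoid-plus-noise vitals streams with
class-dependent mean level and Poisson sensor gaps (uniform 2–10 s, so some
gaps fall on each side of the 5 s interpolation threshold), and a cell
blanking degrader for imputation tests.

What the generator does *not* emulate: realistic waveform morphology,
temporal disease progression, inter-modality correlation structure, label
noise, and non-Gaussian heavy tails. Passing tests therefore demonstrate
that the pipeline recovers class structure a KNN hypergraph can express —
not clinical performance on real cohorts.

## Preprocessing

Mixed-type tables: numeric columns mean-imputed, categoricals mode-imputed
(or sent to an explicit "Unknown" category) and one-hot encoded with
category sets from the fit rows, then z-scored — all statistics from a
caller-designated fit subset so test rows never leak into them. Time series:
strictly sorted timestamps; gaps shorter than 5 s linearly interpolated at
the native (median) sampling interval; fixed 30 s windows that overlap a
longer gap are dropped; per-window mean and population variance are averaged
over retained windows into a length-2 feature vector. No retained windows is
an error, as is a column entirely missing on the fit rows.

## Numerical conventions and edge cases

- Symmetry/PSD assertions: 1e−12 / 1e−8; operator identities: 1e−10;
  loop-vs-matrix equivalence: 1e−8; spectral-filter oracle: 1e−6.
- Argmax ties in prediction resolve to the lowest class index.
- All stochastic operations take explicit seeds or Generators; reports are
  pure functions of (data, config, seed) and serialize to stable JSON.

## Problem sizes used in the shipped experiments

The test suite and acceptance script run: 200–300 random small hypergraphs
(≤ 12 nodes) for algebraic checks; the default 50-subject cohort with
10-fold × 2-repeat CV for the headline comparison; n = 150 balanced cohorts
across 10 seeds with 5-fold CV for signal recovery (mean accuracy ≥ 0.95 at
4 sd separation) and the zero-signal null (accuracy inside the binomial 95%
chance band — balanced classes are used there because only then does the
majority rate equal the chance agreement rate of a non-degenerate
classifier); and n = 90 cohorts with a single informative modality for the
ablation-ordering check. These sizes are the package's chosen study
conditions; everything scales to larger cohorts by the same code paths.

## Known limitations

- Transductive only: adding a subject requires rebuilding the hypergraph and
  retraining (R is node-indexed).
- Unit hyperedge weights; no attention or learned weighting.
- Euclidean KNN only; metric learning is out of scope.
- Dense operators cap practical cohort size at a few thousand nodes.
- The gate mitigates but does not remove oversmoothing at very large L.
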