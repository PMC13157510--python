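# Methods

## The model

`heatconn` implements a heat-kernel diffused multimodal graph isomorphism
network (GIN) for predicting phenotypes (age, sex) from functional
connectomes. Each subject contributes one graph per fMRI modality
(e.g. an emotion-identification task and a working-memory task):

1. **Graph substrate.** The N×N functional-connectivity (FC) matrix is the
   Pearson correlation of ROI-mean BOLD time courses. Node features are the
   rows of the FC matrix (each region's connectivity profile); edge weights
   are cosine similarities between those profiles with negative values
   clipped to zero, sparsified to the top fraction (default 0.15) of edges
   with lexicographic tie-breaks. Negative-similarity clipping keeps the
   Laplacian well defined — diffusion theory assumes nonnegative weights.
2. **Diffusion.** With L = D − A the combinatorial graph Laplacian, the heat
   kernel K_β = exp(−βL) is computed by full eigendecomposition (eigenpairs
   are reused across β values; N is at most a few hundred). Node features
   are diffused, H₀ = K X, which smooths each profile over its graph
   neighbourhood. A truncated Chebyshev/Taylor kernel is provided as a
   scalability path and reports its deviation from the exact kernel.
3. **Message passing.** Each of K GIN layers computes
   MLP((1+ε)·h_v + Σ_u w_vu h_u), where the neighbour weights w are the
   off-diagonal heat-kernel entries — a smooth weighting of the sum
   aggregation. The self term always carries weight (1+ε); the kernel
   diagonal is excluded to avoid double counting. The MLP is two dense
   transforms with a ReLU between.
4. **Readout and fusion.** Graph-level vectors are node sums per layer
   (layer 0 = diffused input), concatenated across layers, then across
   modalities in declared order, scaled by 1/N (sum readouts grow with N),
   and passed through a ReLU dense head. The output layer is
   zero-initialized so age predictions start at the training mean and sex
   probabilities at 0.5.
5. **Objective.**
   `L = Σ_m ‖K^(m) − A^(m)‖_F² + λ · Σ_i loss(y_i, ŷ_i)`
   with mean-squared error for age and binary cross-entropy for sex (the
   standard losses behind the reported RMSE/MAE/r and ACC/AUC/F1 metrics),
   summed over subjects. The reconstruction term has gradient flow only
   through the diffusion scale, so β is learnable by default
   (softplus-parameterized); the term then keeps exp(−βL) from drifting
   toward the over-smoothed constant kernel. λ defaults to 1.

**Kernel-off arm.** β = 0 disables the kernel entirely: diffusion is the
identity and aggregation reverts to the original adjacency weights. This
single code path is simultaneously the plain-GIN baseline (identical
predictions by construction, which the tests assert) and the "no heat
kernel" ablation arm, whose kernel slot is verifiably the identity.

**Autodiff.** The model, its training loop, the dense baseline and the
explainer all run on a small in-repo reverse-mode autodiff engine over
numpy arrays (`heatconn.autodiff`), sufficient for the dense linear algebra
involved; gradients are verified against central finite differences in the
test suite (relative error ≤ 1e-4).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `beta` | 1.0 (learnable) | diffusion time; small = local smoothing, large → constant kernel |
| `density` | 0.15 | fraction of cosine-similarity edges kept |
| `hidden_dim` | 100 | GIN MLP width (reference full-scale setting) |
| `n_gin_layers` | 2 | message-passing depth |
| `lam` | 1.0 | reconstruction vs supervised balance |
| `learning_rate` / `epochs` / `weight_decay` | 1e-5 / 3000 / 0.2 | reference full-scale training setting (adaptive-moment, decoupled decay) |

The desk-scale protocols (`heatconn.protocols`) use hidden width 16, fixed
β = 0.05, learning rate 1e-2 for 100 epochs, weight decay 1e-3. These were
chosen by validation on the synthetic cohort: the cosine graphs have
weighted degree ≈ 7, so exp(−0.05·L) mixes roughly a third of each node's
mass into its neighbourhood — enough denoising to help without blurring
the block structure that carries the signal. The problem sizes (400
subjects, 60 ROIs, 10 seeds) keep a full study in minutes on one CPU.

## The synthetic cohort

The simulator emulates the statistical shape of an adolescent two-task
fMRI cohort: ages uniform on [8, 22] with five equal-width developmental
stages (the stage definition used by the source cohort is not public, so
equal-width bins stand in), balanced sexes, 124 time points, and ROIs
grouped into Power-style functional systems. Effects are planted in the
correlation domain: within-network blocks at base correlation 0.35; a
monotone age effect (+0.015/yr) on the FRNT–MEM and FRNT–SAL inter-network
blocks; an additive ±0.08 sex effect on a designated 40-edge subset
disjoint from the age blocks; a per-subject random effect (sd 0.02) whose
two modality components correlate at 0.6. Targets are projected to the
nearest valid correlation matrix (eigenvalue clipping at 1e-6, diagonal
renormalization; an error is raised if the projection moves any planted
entry by more than 0.05). BOLD series are drawn from a zero-mean
multivariate normal with the planted correlation plus white observation
noise (sd 0.25 against unit-variance signal), and FC is recomputed through
the same Pearson pipeline as real data. At these settings single-edge
between-subject reliability is ≈ 0.3, in the range reported for task-fMRI
connectivity.

What it does **not** emulate: hemodynamic autocorrelation, motion and
physiological artifacts, site effects, or inter-individual variation in
network topography. Passing recovery tests therefore show that the
pipeline can extract planted, block-structured signals under sampling
noise — not that it matches real-data accuracy.

## Evaluation protocols

Splits are 80/20 holdouts or 10-fold cross-validation, each repeatable
with independent shuffles, stratified by sex for classification; all
splits, initializations and simulations are driven by explicit seeds, and
repeated runs with the same configuration are byte-identical. Ablation
grids (kernel on/off × modality subsets) reuse identical splits across
arms. Model comparisons use two-sided paired t-tests on per-repeat metric
series; zero-variance differences raise an error rather than returning a
degenerate p-value. The kernel-on/kernel-off comparison in the bundled
protocol averages two paired initializations per arm, because single-init
differences (~±0.02 in r) are comparable to the kernel effect itself
(~+0.03 at these conditions).

Baselines: least-squares/logistic regression and a dropout+L2 dense
network on the vectorized upper-triangular FC, plus the plain GIN.

## Explainer

GNNExplainer-style mask optimization: a symmetric edge mask in [0,1]^{N×N}
(zero diagonal) and a feature mask in [0,1]^d, both sigmoid-parameterized
with zero-initialized logits (deterministic and permutation-equivariant),
optimized by the adaptive-moment method. The edge mask multiplies the
off-diagonal entries of the kernels the model aggregates with — masking
the operator masks exactly the computation-graph edges the model uses, and
avoids a matrix-exponential backward pass. The objective is masked-graph
fidelity (squared error against the frozen model's prediction for age;
cross-entropy against its hard label for sex) plus size (mean) and element
(binary entropy) penalties on both masks; an MSE form of the feature
penalty is selectable.

The stored defaults reproduce the reference weighting (prediction 1,
feature size 200, feature element 20, population size 0, population
element 1000, 100 epochs, lr 0.5). That weighting places no sparsity
pressure on the edge mask, and on the desk-scale synthetic models the
fidelity term is then satisfied by keeping every edge, so the mask cannot
select a subgraph. The bundled synthetic protocol therefore uses a
calibrated weighting (prediction 1, edge size 50, edge entropy 1, feature
size 1, feature element 0.1) — explainer hyperparameters are tuned per
dataset in practice, and this calibration recovers planted edges at ~5–10×
the chance rate.

Edge scores live on the upper triangle; top-k% extraction uses the floor
rule k = ⌊pct/100 · N(N−1)/2⌋ with lexicographic tie-breaks, at subject,
stage (intersection of members' top sets) or cohort (mean mask) scope.

## Numerical choices and degenerate inputs

- Kernel entries below 1e-12 are truncated to zero (eigen-reconstruction
  dust); kernels are explicitly symmetrized.
- Pearson r of a constant vector, and AUC with a single class, are
  reported as NaN markers rather than silent zeros.
- Zero-variance ROI rows, negative edge weights, asymmetric inputs,
  missing modalities and unknown atlas labels all raise typed errors
  naming the offending entity.
- Disconnected sparsified graphs are allowed but logged with their
  component count; the normalized Laplacian zeroes isolated-node rows.
- Ties in edge sparsification and edge ranking break lexicographically by
  (i, j), making outputs stable across platforms.

## Known limitations

- The exact kernel path is O(N³) per graph; beyond a few hundred ROIs the
  Chebyshev approximation should be used.
- Full-batch training only; the reference 3000-epoch setting is slow on
  large cohorts in pure numpy.
- The explainer explains one subject at a time; population-level masks are
  aggregations of per-subject masks rather than jointly optimized.
- Synthetic validation covers planted block signals only (see above).
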