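# Methods

## Model overview

`scecda` clusters paired single-cell multi-omics data (any combination of
RNA, ATAC and ADT layers measured in the same cells) end to end. The
pipeline has three stages:

1. **Per-omics feature extraction.** Each modality u gets its own
   fully-connected autoencoder; the encoder E^u maps the preprocessed
   matrix X^u ∈ R^{n×m_u} to latent features Z^u ∈ R^{n×d_u} and is
   pretrained by minimizing the mean squared reconstruction error
   ‖X^u − D^u(E^u(X^u))‖², summed over modalities.
2. **Smoothing, alignment and fusion.** Latent features pass through a
   Student-t style kernel around per-omics cluster centers ξ^u, giving
   row-stochastic soft assignments
   q^u_{ij} ∝ (1 + ‖z^u_i − ξ^u_j‖)⁻¹.
   A contrastive loss over cross-omics and augmented views of the q rows
   aligns modalities cell-by-cell, with an entropy regularizer
   Σ_u Σ_j ρ^u_j log ρ^u_j on the batch-mean cluster usage discouraging
   collapse. Concatenated latents Z = [Z¹,…,Z^v] are fused by
   differential attention over cells:
   O = {softmax(G₁K₁ᵀ/√f) − λ·softmax(G₂K₂ᵀ/√f)} Z′, followed by
   LayerNorm, a residual connection and a linear transform to give fused
   features H of the same shape as Z. λ is a learnable scalar
   reparameterized as λ = exp(λ_g1·λ_k1) − exp(λ_g2·λ_k2) + 0.8 −
   0.6·exp(−0.3·λ₀).
3. **Clustering.** A linear head gives soft probabilities
   A = softmax(HW₅); the sharpened, frequency-corrected target
   P_ij = (A_ij²/f_j)/Σ_{j'}(A_ij'²/f_j'), f_j = Σ_i A_ij, is aligned
   with each modality's soft assignment through
   L_stage3 = (1/v) Σ_u KL(P‖q^u). Labels are c_i = argmax_j P_ij.

The total objective is L = α·L_stage1 + β·L_stage2 + γ·L_stage3 with
defaults α=1, β=1, γ=0.5, optimized with Adam over mini-batches.

All neural components run on a small reverse-mode autograd engine over
NumPy arrays (`scecda.autograd`); gradient correctness is property-tested
against finite differences. Standard surrounding steps use established
libraries: scanpy/AnnData for preprocessing, scikit-learn for PCA, K-means,
ARI/NMI and silhouette, SciPy for Hungarian matching and Matrix Market IO.

## Key design choices

**Target distribution handling.** L_stage3 is the only loss term that
touches the fused features, so how P enters the optimization matters. We
evaluated two designs. Differentiating through P (so the KL term trains the
attention block and W₅ end to end) destabilizes training: the unsquared
soft-assignment kernel yields flat q rows at the latent scales typical of
standardized inputs, the KL between a sharp target and a flat assignment is
irreducible, and its large gradients churn the cluster head without
improving it. The shipped default instead treats P as a *stale* target:
it is recomputed from the full dataset every `target_interval` epochs
(default 1) and held constant within the interval, the standard
self-training scheme of deep embedded clustering. Gradients then flow into
the encoders and the (trainable) centers through q^u. The fully
differentiable variant remains available via `TrainConfig.attach_target`.

**Head and center initialization.** Two initialization steps are essential
and cheap. First, K-means indexes clusters arbitrarily per modality, so the
per-omics centers are permutation-matched to modality 0 by Hungarian
matching on the overlap of hard assignments — without this, the KL and
contrastive terms compare mismatched cluster columns. Second, W₅ is warmed
up by distilling a K-means partition of the full-dataset fused features H
(the usual initialization of a deep-embedded-clustering layer), with the
one-hot partition softened to the consensus assignment's mean sharpness so
the head starts at the scale the KL term expects. The K-means cluster ids
are Hungarian-matched to the consensus soft assignment before distillation.

**Soft-assignment kernel.** The default kernel uses the unsquared Euclidean
norm, (1 + ‖z−ξ‖)⁻¹. The squared DEC convention (1 + ‖z−ξ‖²)⁻¹ is available
via `squared_distance=True`. On the synthetic fixtures the unsquared kernel
is also the more robust choice: a modality carrying no signal produces
near-uniform assignments under it, which barely perturb the consensus,
whereas the squared kernel sharpens those spurious assignments.

**Quality filter.** Before center initialization each modality's latent
matrix is projected to 40 principal components; cells whose nearest-neighbor
distance exceeds the Tukey fence Q3 + 1.5·IQR (type-7 quartiles,
self-distances excluded) are excluded from K-means. The comparison includes
a ~1e-9 relative tolerance so exact-boundary cells are not dropped by PCA
round-off. With fewer than 3 cells, filtering is disabled.

**Contrastive composition.** Positive pairs per cell: all unordered clean
cross-omics pairs plus all ordered augmented–clean cross pairs (for a single
modality, the augmented–clean pair). Negatives: all view pairings with other
cells in the batch (clean–clean, augmented–clean, clean–augmented). The loss
is the InfoNCE composition with cosine similarity at temperature τ = 1;
a literal "ratio" variant −log(d⁺/(d⁺+d⁻)) that sums similarities before
exponentiation is available behind a flag. Features are the q rows, not the
raw latents. With a batch of one cell the negative set is empty and the
term degenerates to zero.

**Fusion dimensions.** The value projection W₃ and output transform W₄ map
Σd_u → Σd_u so the residual connections O′ = Norm(Z+O) and H = Norm(O′W₄+O′)
are well-typed for any number of modalities; H always has the shape of the
concatenated latents. Norm is non-affine per-row LayerNorm. λ's dot products
are clamped to ±20 before exponentiation.

**Training-stage scaling.** Inside the joint loop, L_stage1 is the mean
(not summed) squared error and L_stage3 is divided by the batch size, so the
three loss terms are all per-cell quantities and the published weights
(1, 1, 0.5) weigh comparable magnitudes.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `hidden_dims` | 64 | latent width d_u per modality |
| `encoder_widths` | (500, 500, 2000) | hidden-layer widths of the published architecture |
| `batch_size` | 256 | mini-batch size for both stages |
| `pretrain_epochs` / `train_epochs` | 50 / 200 | stage budgets; joint training stops early on label stability |
| `pretrain_lr` / `lr` | 1e-3 / 5e-4 | Adam step sizes (chosen on the synthetic fixtures; the source method does not fix them) |
| `convergence_tol` | 0.001 | stop when fewer than 0.1% of labels change between refreshes |
| `dropout_p`, `eps_sigma` | 0.1, 0.1 | latent augmentation: dropout rate and Gaussian perturbation scale |
| `tau` | 1.0 | contrastive temperature |
| `two_f` | 256 | total query/key projection width (f = 128 per map) |
| `lambda0` | 5.0 | λ initialization constant, in (0, 10) |
| `alpha, beta, gamma` | 1, 1, 0.5 | loss weights |
| `n_hvg` | 4000 RNA / 2000 ATAC / none ADT | highly variable features retained |
| `min_cells` | 2 | minimum cells expressing a feature |

The tests and the acceptance script use narrower layers
(`encoder_widths=(256,)`, `hidden_dims=32`, 40 pretraining and up to 100
joint epochs) sized to the synthetic fixtures' ~100 features; a 2000-unit
layer is not warranted at that input width.

## Synthetic data generator

The generator draws y* cluster means on orthonormal random directions in a
10-dimensional latent space, scaled so every pair of means is `separation`
apart; per-cell latent noise is unit scale, making `separation` a direct
signal-to-noise knob (5 = moderate, 10 = well separated). Each modality
mixes the true latent with pure unclustered noise of matched marginal scale
according to `informativeness` (1 = full signal, 0 = none), maps the result
through a fixed random linear map and softplus to non-negative rates, then
samples its observation model: Gaussian, log-normal, negative binomial
counts (dispersion 1, mean ≈ `nb_mean`), or binarized detection
(ATAC-like). `dropout_rate` sets the target total zero fraction; Bernoulli
dropout is calibrated on top of intrinsic sampling zeros. The
partial-information scenario generates four balanced clusters of which each
of the first two modalities resolves only a coarse two-group split
({0,1} vs {2,3} and {0,2} vs {1,3}); the full structure is identifiable
only jointly.

What the generator does *not* emulate: batch effects, count overdispersion
heterogeneity across genes, doublets, ambient contamination, trajectories,
or realistic gene–gene correlation. Passing tests therefore demonstrate the
mechanics and the integration behavior of the method, not performance on
any real dataset.

## Evaluation metrics

ARI, NMI (geometric-mean normalization), clustering accuracy (Hungarian
matching on the contingency table) and purity score label agreement; all
four are invariant to cluster relabeling. cASW is the mean silhouette of
the true cell types in the fused feature space, reported on the raw [−1, 1]
scale. cLISI computes each cell's inverse Simpson's index of type
composition in a perplexity-weighted Gaussian neighborhood (perplexity 30,
neighbor cap 3×perplexity, per-cell bandwidth by bisection); the median is
rescaled as (n_types − LISI)/(n_types − 1) so 1 means label-pure
neighborhoods. Aggregates: cluster_avg = (ARI+NMI+ACC+PUR)/4,
bio_avg = (cLISI + cASW)/2, performance = mean of all six. Because cASW is
kept on its raw scale, bio_avg and performance can sit well below the
label metrics even for a perfect clustering; an `(s+1)/2` rescale would be
needed to read them on [0, 1].

## Numerical choices

Probabilities are floored at 1e-12 inside logarithms and KL terms; row
norms in cosine similarities are floored at 1e-12; softmax subtracts the
row maximum; distances pass through max(·, 0) before the square root with
a 1e-12 regularizer at zero; empty-cluster frequencies in P are floored at
1e-12. Argmax ties break to the lowest index. All computation is float64.
Non-finite losses or activations abort with diagnostics rather than
propagate.

## Known limitations

- The number of clusters y must be supplied by the user.
- With the stale-target default, the attention parameters and λ change only
  through their initialization and the warm-up distillation; enabling
  `attach_target` trains them end to end at the cost of stability on flat
  assignment profiles.
- Quality filtering runs once after pretraining, not per epoch.
- Attention is computed per mini-batch during training and over the full
  dataset at inference; very small trailing batches therefore see slightly
  different attention statistics.
- No batch-effect term: multi-batch integration relies on the shared latent
  structure only.
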