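# Methods

## Problem and model

Sequencing-based spatial transcriptomics (ST) platforms such as 10x Visium
measure expression at capture spots that each contain a mixture of cells.
`spotae` estimates, for every spot, the proportion of each cell type
contributing to its expression, without requiring predefined marker genes:
cell-type signatures are *learned* jointly with the proportions.

The model is an autoencoder over spot expression profiles
`X ∈ R^{ns×ng}` whose latent width equals the number of cell types `k`:

* encoder `ψ_θ : R^{ng} → R^{k}`, an MLP (default `ng → 512 → 128 → k`)
  with ELU hidden activations and a **softplus** output, so the latent code
  `Z = ψ_θ(X)` is nonnegative;
* decoder `φ_ϑ : R^{k} → R^{ng}`, a **single bias-free linear map**. Its
  `k × ng` weight matrix is the cell-type-by-gene signature: decoding the
  one-hot latent vector `e_t` returns exactly row `t`. A deeper or biased
  decoder would break this exact interpretability, which is the point of
  the architecture.

Spatial structure enters through a KNN graph over spot coordinates with
Laplacian `L = D − W`; the regularizer `Tr(ZᵀLZ) = ½ Σ_ij W_ij‖z_i − z_j‖²`
penalizes latent differences between spatial neighbors.

Training is two-stage over one shared parameter set:

1. **Supervised stage** on pseudo-spots simulated from a labeled
   single-cell reference, whose true compositions `P` are known:

   `min mean|X_s − φ(ψ(X_s))| + mean|P − Z| + α · Tr(ZᵀL_s Z)/ns`

2. **Adaptation stage** on the target ST data, where compositions are
   unknown, dropping the supervision term:

   `min mean|X_r − φ(ψ(X_r))| + α · Tr(ZᵀL_r Z)/ns`

The final proportions are the row-normalized latent code (each row of `Z`
divided by its sum; an all-zero row falls back to uniform `1/k`).

### Loss reductions

Each L1 term is the **mean** absolute deviation over its entries and the
Laplacian trace is averaged per spot. This is a deliberate design choice:
with raw entrywise sums the reconstruction term has `ns·ng` entries against
the supervision term's `ns·k`, so for any realistic gene count the
supervision is asymptotically irrelevant — on the package's own benchmark
the summed objective is *minimized* by a latent code that ignores `P`
(lower total loss than the P-aligned solution), and recovery fails. Mean
reduction keeps the three terms on comparable scales regardless of `ng`,
and is also the default reduction of the major deep-learning frameworks'
L1 losses. The reductions interact with the learning rate only through
Adam's per-parameter normalization, which largely absorbs them.

Supervision targets the raw nonnegative `Z`, not its row-normalized form:
rows of `P` already sum to one, so the optimum drives `Z` onto the simplex
directly, and the gradient stays simple.

## Spatial graph

* K nearest neighbors per spot by Euclidean distance (default `k = 6`,
  the spot adjacency count of hexagonal capture arrays), self excluded,
  exact distance ties broken by spot index.
* Coordinates are used as given — no per-axis rescaling, which would
  distort isotropy on non-square fields and perturb exact ties.
* Edge weights `w_ij = exp(−d_ij / d̄)` where `d̄` is the mean directed
  KNN-edge distance. Dividing by `d̄` makes the weights invariant to
  coordinate units (pixels, microns, grid indices). Duplicate coordinates
  get weight 1.
* The directed KNN relation is symmetrized by elementwise max, keeping
  every stated neighbor edge; the Laplacian is the unnormalized `D − W`.

## Preprocessing

* Highly variable genes are ranked by the Seurat-v3-style
  variance-stabilizing statistic: a loess-type fit of log10 variance on
  log10 mean (statsmodels lowess, `frac = 0.3` — a locally linear
  approximation of the usual degree-2 loess), counts clipped at
  `mean + √N · regularized sd`, then the standardized variance. Default
  `n_top = 5000` for single-cell references. Ties, including all-zero
  genes (statistic 0), break lexicographically by gene id so the ranking
  is invariant to row and column order.
* Library-size normalization to `1e4` per observation (the scanpy/Seurat
  convention), then `log1p`. Zero-count rows are left as zeros with a
  logged warning.
* Per-gene scaling to mean 0 / unit variance (sample sd, `ddof = 1`;
  zero-variance genes set to 0) is applied **after** the simulated and
  target gene axes are aligned (intersection, sorted lexicographically),
  so the encoder sees one consistent feature scale. Each dataset is scaled
  on its own statistics.

## Synthetic benchmark generator

`generate_reference` draws negative-binomial counts (baseline mean 1,
dispersion 2 — overdispersion typical of UMI counts) for `k` cell types,
each over-expressing a disjoint block of marker genes by a fold change.
`simulate_spots` places spots on a regular grid partitioned into `k`
contiguous domains (stripes or blocks), draws each spot's composition from
a Dirichlet whose concentration is `purity` on the domain's dominant type
and 1 elsewhere, samples that many cells with replacement, and sums their
counts. The recorded ground truth is the *realized* sampled-cell fraction,
so `P` is exactly consistent with the aggregated expression; the sampled
cell indices are kept in the provenance so any spot can be re-derived
bit-exactly.

Defaults (4 types, 20 markers/type at 10× fold, 200 cells/type, 20 × 10
grid, 10 cells/spot — a typical Visium occupancy scale, stripe domains,
purity 5) give a strong-signal benchmark with spatially coherent
compositions: the two properties the spatial regularizer and the
supervision respectively rely on. The generator deliberately does **not**
model dropout, batch effects, correlated gene programs, platform-specific
noise, or continuous gradients between domains — passing tests show the
method recovers compositions when types are separable and domains are
coherent, not that it is robust to those real-data complications.

## Optimization and numerical choices

* Full-batch Adam (β = 0.9/0.999, ε = 1e-8), learning rate 1e-4. The
  Laplacian term couples all spots, so mini-batching would need subgraph
  Laplacians; spot counts are small enough that full batches are cheap.
* L1 subgradients taken as `sign(·)`; exact zeros contribute 0.
* Initialization: fan-in uniform `U(±1/√fan_in)`; all randomness flows
  through one `numpy` generator seeded from the config, so CPU runs are
  bit-reproducible.
* Epochs: 4000 (stage 1) + 2000 (stage 2) by default, with early stopping
  when the loss changes by < 1e-5 (relative) over a 200-epoch window.
  These counts were chosen so the default benchmark trains to (or near)
  that plateau; at half the epochs the objective is still visibly
  descending and recovery is measurably worse.
* Stage 2 restarts the Adam moment estimates (the objective changes);
  `epochs_stage2 = 0` is an exact no-op.
* A non-finite loss aborts with a diagnostic naming the offending term.

## Evaluation metrics

* **PCC** per cell type across spots; reported as mean ± sd over types.
  Zero-variance columns score 0 with a warning (the raw signed values are
  what the vector holds otherwise).
* **SSIM** per cell type: the proportion field is rasterized to the
  integer lattice nearest each coordinate (error if two spots collapse
  onto one cell), min-max scaled to [0, 1] per image, then
  Gaussian-weighted SSIM (σ = 1.5, C1 = 0.01², C2 = 0.03², data range 1),
  with the half-window border cropped before averaging as in the standard
  implementation; rasters smaller than the 11-pixel window fall back to
  the full-map mean.
* **JSD** per spot, natural log (range [0, ln 2]; `base="2"` available);
  rows off the simplex by > 1e-6 are renormalized with a warning.
* **RMSE** pooled over all `ns·k` entries; **Frobenius** distance obeys
  `frobenius = rmse·√(ns·k)` (used as a cross-check).
* **ARI** (chance-corrected pair counting, via scikit-learn) and
  **purity** for domain labelings.
* **Moran's I** and **Geary's C** with the spatial-graph weights, the
  standard centered formulas; constant fields raise (undefined).

## Limitations

* The model is reconstruction-driven; heavy noise or strong
  batch/platform shift between the reference-derived pseudo-spots and the
  target data degrades the shared encoder and is not corrected for.
* One latent dimension per type means rare types compete with abundant
  ones for reconstruction mass; rare-type calibration is out of scope.
* The benchmark generator's simplifications (above) bound what the test
  suite demonstrates about real tissue.
* Only spot coordinates inform the spatial graph; histology is not used.
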