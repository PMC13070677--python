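# spotae

Cell-type deconvolution of spatial transcriptomics (ST) spots with a
graph-regularized autoencoder.

Sequencing-based ST platforms (10x Visium, Legacy ST) measure expression at
capture spots that each mix several cells, so downstream analyses — spatial
domains, micro-environments, spatially informative genes — need per-spot
**cell-type proportions**. Most deconvolution tools require predefined
cell-type marker genes or fixed reference signatures. `spotae` instead
*learns* signatures jointly with the proportions: a labeled single-cell
reference is used only to simulate pseudo-spots with known compositions for
supervised pretraining, after which the model adapts to the real data by
reconstruction alone. It is intended for computational biologists analyzing
spot-level ST with a matched (or tissue-compatible) labeled scRNA-seq
reference.

## Model

For spot expression `X ∈ R^{ns×ng}` with coordinates `Y ∈ R^{ns×2}`, an
encoder `ψ_θ` maps each spot to a nonnegative latent code
`Z = ψ_θ(X) ∈ R^{ns×k}` with one dimension per cell type; a bias-free linear
decoder `φ_ϑ` reconstructs expression, so its `k × ng` weight matrix is
directly the learned cell-type-by-gene signature. A KNN spatial graph over
`Y` (k = 6 neighbors, edge weights `exp(−d/d̄)`) contributes a Laplacian
smoothness penalty. The two training stages minimize

```
stage 1 (simulated spots, known P):  mean|X_s − φ(ψ(X_s))| + mean|P − Z| + α·Tr(ZᵀL_s Z)/ns
stage 2 (target spots):              mean|X_r − φ(ψ(X_r))| + α·Tr(ZᵀL_r Z)/ns
```

with α = 0.1 by default and full-batch Adam (lr = 1e-4). Row-normalizing
`Z` gives the proportion estimates. See `docs/methods.md` for assumptions,
parameter rationale, and limitations.

## Worked example

Simulate a strong-signal benchmark (4 cell types, 20 marker genes each at
10× fold, 800-cell reference; 200 pseudo-spots on a 20×10 grid in 4 stripe
domains), train both stages with defaults, and score the recovered
proportions against the known ground truth:

```python
import numpy as np
import spotae

run = spotae.run_benchmark(seed=1)          # simulate + preprocess + 2-stage fit (~1 min)
score = spotae.evaluate(
    run.result.proportions, run.sim_raw.P,
    coords=run.sim_raw.st.coords, type_names=run.sim.type_names,
)
print(f"mean PCC : {score.pcc_mean:.3f} +/- {score.pcc_sd:.3f}")
print(f"mean SSIM: {np.mean(score.ssim_per_type):.3f}")
print(f"mean JSD : {score.jsd_mean:.3f}")
print(f"RMSE     : {score.rmse:.3f}")
```

prints

```
mean PCC : 0.843 +/- 0.023
mean SSIM: 0.525
mean JSD : 0.063
RMSE     : 0.167
```

i.e. the predicted per-type proportion profiles correlate with the truth at
0.84 on average across the four types (1.0 would be perfect), the per-spot
compositions are close in distribution (JSD well below its ln 2 ≈ 0.69
maximum), and the entrywise error is ~0.17 on proportions in [0, 1].
`run.result.signatures` holds the learned signatures; on this benchmark
each type's signature peaks inside that type's marker-gene block.

The same pipeline is available from the shell:

```sh
spotae simulate --seed 1 --out sim/
spotae train --simulated sim/simulated.h5ad --out fit/ --seed 1
spotae deconvolve --checkpoint fit/checkpoint.npz --out dec/
spotae evaluate dec/proportions.csv sim/simulated.proportions.csv
```

Real data enter through `spotae.read_st` (h5ad with `obsm["spatial"]`,
MatrixMarket directory, or CSV) and `spotae.read_reference` (h5ad with
`obs["cell_type"]`), with `--real-st` on `spotae train` for the
stage-2 target.

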