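"""End-to-end orchestration: simulate -> preprocess -> train -> deconvolve -> evaluate.

These helpers wire the modules together the way the CLI and the benchmark
scripts use them. The preprocessing order is: library-size normalize and
log-transform each dataset on its own, align the simulated and target gene
axes, then scale per gene within each dataset — so the encoder sees one
consistent feature scale on a shared gene axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Any

import numpy as np

from .io_prep import ExpressionMatrix, STDataset, align_genes, preprocess, select_hvg
from .model import (
    DeconvResult,
    SpotAutoencoder,
    TrainConfig,
    deconvolve,
    fit_stage1,
    fit_stage2,
)
from .simulate import LabeledReference, SimulatedST, generate_reference, simulate_spots
from .spatial_graph import build_spatial_graph


def _scaled(expr: ExpressionMatrix) -> ExpressionMatrix:
    mu = expr.values.mean(axis=0)
    sd = expr.values.std(axis=0, ddof=1) if expr.values.shape[0] > 1 else np.zeros(expr.n_genes)
    X = expr.values - mu[None, :]
    nz = sd > 0
    X[:, nz] /= sd[None, nz]
    X[:, ~nz] = 0.0
    return ExpressionMatrix(X, list(expr.obs_ids), list(expr.gene_ids), "scaled")


def prepare_pair(
    sim: SimulatedST, real: STDataset | None = None
) -> tuple[SimulatedST, STDataset | None]:
    """Normalize + log each dataset, align gene axes, then scale per gene."""
    sim_norm = preprocess(sim.st.expr, do_scale=False)
    if real is None:
        expr = _scaled(sim_norm)
        st = STDataset(expr, sim.st.coords)
        return SimulatedST(st, sim.P, list(sim.type_names), dict(sim.provenance)), None
    real_norm = preprocess(real.expr, do_scale=False)
    sim_aligned, real_aligned = align_genes(sim_norm, real_norm)
    sim_st = STDataset(_scaled(sim_aligned), sim.st.coords)
    real_st = STDataset(_scaled(real_aligned), real.coords)
    return (
        SimulatedST(sim_st, sim.P, list(sim.type_names), dict(sim.provenance)),
        real_st,
    )


def train_two_stage(
    sim: SimulatedST,
    cfg: TrainConfig,
    real: STDataset | None = None,
) -> tuple[SpotAutoencoder, STDataset, list[float], list[float]]:
    """Run both training stages and return the model plus loss traces.

    ``sim`` must carry preprocessed (scaled) expression, e.g. from
    :func:`prepare_pair`. When ``real`` is None the simulated data itself is
    the deconvolution target and stage 2 adapts to it without labels.
    """
    target = real if real is not None else sim.st
    model = SpotAutoencoder(
        ng=sim.st.expr.n_genes,
        type_names=sim.type_names,
        hidden_dims=cfg.hidden_dims,
        seed=cfg.seed,
        gene_ids=list(sim.st.expr.gene_ids),
    )
    sim_graph = build_spatial_graph(sim.st.coords, cfg.k_neighbors)
    model, trace1 = fit_stage1(model, sim, sim_graph, cfg)
    target_graph = (
        sim_graph if target is sim.st else build_spatial_graph(target.coords, cfg.k_neighbors)
    )
    model, trace2 = fit_stage2(model, target, target_graph, cfg)
    return model, target, trace1, trace2


@dataclass
class BenchmarkRun:
    """Everything a benchmark produces: data, model, prediction, provenance."""

    reference: LabeledReference
    sim_raw: SimulatedST
    sim: SimulatedST
    model: SpotAutoencoder
    result: DeconvResult
    config: TrainConfig
    params: dict[str, Any] = field(default_factory=dict)


def run_benchmark(
    seed: int = 0,
    k: int = 4,
    n_per_type: int = 200,
    ng: int = 200,
    n_markers_per_type: int = 20,
    fold: float = 10.0,
    grid: tuple[int, int] = (20, 10),
    cells_per_spot: int = 10,
    domain_layout: str = "stripes",
    purity: float = 5.0,
    n_hvg: int | None = None,
    cfg: TrainConfig | None = None,
) -> BenchmarkRun:
    """Full synthetic benchmark: reference, pseudo-spots, two-stage fit, deconvolution.

    Defaults give a strong-signal benchmark: 4 cell types with 20 markers
    each at 10x fold in an 800-cell reference, 200 spots (20 x 10 grid, 10
    cells each) arranged in 4 stripe domains with Dirichlet purity 5.
    Sub-seeds for the reference, the spot sampler, and the network
    initialization are all derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seed_ref, seed_spots, seed_net = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    ref = generate_reference(
        k=k, n_per_type=n_per_type, ng=ng,
        n_markers_per_type=n_markers_per_type, fold=fold, seed=seed_ref,
    )
    if n_hvg is not None:
        hvg = select_hvg(ref.expr, n_hvg)
        ref = LabeledReference(ref.expr.subset_genes(hvg), list(ref.labels), list(ref.type_names))
    sim_raw = simulate_spots(
        ref, grid=grid, cells_per_spot=cells_per_spot,
        domain_layout=domain_layout, purity=purity, seed=seed_spots,
    )
    cfg = replace(cfg, seed=seed_net) if cfg is not None else TrainConfig(seed=seed_net)

    sim, _ = prepare_pair(sim_raw)
    model, target, trace1, trace2 = train_two_stage(sim, cfg)
    result = deconvolve(model, target, loss_trace=trace1 + trace2, config=cfg)
    params = dict(
        seed=seed, k=k, n_per_type=n_per_type, ng=ng,
        n_markers_per_type=n_markers_per_type, fold=fold, grid=grid,
        cells_per_spot=cells_per_spot, domain_layout=domain_layout, purity=purity,
    )
    return BenchmarkRun(
        reference=ref, sim_raw=sim_raw, sim=sim, model=model,
        result=result, config=cfg, params=params,
    )
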