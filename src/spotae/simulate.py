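"""Ground-truth benchmarks: synthetic references and pseudo-spot simulation.

Two generators:

* :func:`generate_reference` draws a labeled single-cell count matrix from a
  negative-binomial model in which each cell type over-expresses a disjoint
  block of marker genes by a configurable fold change. It emulates the one
  property deconvolution relies on — cell types are separable in expression —
  without modelling dropout, batch effects or correlated gene programs.
* :func:`simulate_spots` aggregates labeled cells into pseudo-spots on a
  regular grid. The grid is partitioned into contiguous spatial domains
  (stripes or blocks), each dominated by one cell type; per-spot compositions
  are drawn from a Dirichlet centered on the domain's dominant type, cells
  are sampled with replacement accordingly, and the spot's expression is the
  exact sum of the sampled cells' counts. The recorded ground truth P is the
  *realized* sampled-cell fraction, so P is exactly consistent with the
  aggregated expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import anndata as ad
import numpy as np
import pandas as pd

from .io_prep import ExpressionMatrix, LabeledReference, STDataset

#: Negative-binomial baseline mean per gene.
NB_MEAN = 1.0
#: Negative-binomial dispersion (variance = mu + mu^2 / NB_DISPERSION).
NB_DISPERSION = 2.0


@dataclass
class SimulatedST:
    """A simulated ST dataset with known spot compositions.

    ``P`` holds realized per-spot cell-type fractions (rows on the simplex);
    ``provenance`` records the seed, generator parameters, and the sampled
    cell indices per spot so any spot's expression can be re-derived exactly.
    """

    st: STDataset
    P: np.ndarray
    type_names: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.shape != (self.st.n_spots, len(self.type_names)):
            raise ValueError("P must be (n_spots, k)")
        if self.P.min() < 0:
            raise ValueError("P must be nonnegative")
        if np.abs(self.P.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("P rows must sum to 1")


def generate_reference(
    k: int = 4,
    n_per_type: int = 200,
    ng: int = 200,
    n_markers_per_type: int = 20,
    fold: float = 10.0,
    seed: int = 0,
) -> LabeledReference:
    """Draw a synthetic labeled single-cell reference with marker-gene blocks.

    Counts for cell ``i`` of type ``t`` are negative binomial with mean
    ``NB_MEAN`` everywhere except type ``t``'s marker block (genes
    ``t*m .. (t+1)*m``), whose mean is multiplied by ``fold``.
    """
    if k < 1 or n_per_type < 1 or ng < 1:
        raise ValueError("k, n_per_type and ng must be positive")
    if n_markers_per_type < 0 or k * n_markers_per_type > ng:
        raise ValueError("need k * n_markers_per_type <= ng")
    if fold < 1:
        raise ValueError("fold must be >= 1")

    rng = np.random.default_rng(seed)
    type_names = [f"type_{t}" for t in range(k)]
    n_cells = k * n_per_type

    mean = np.full((n_cells, ng), NB_MEAN)
    labels: list[str] = []
    for t in range(k):
        rows = slice(t * n_per_type, (t + 1) * n_per_type)
        cols = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        mean[rows, cols] *= fold
        labels += [type_names[t]] * n_per_type

    r = NB_DISPERSION
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.float64)
    expr = ExpressionMatrix(
        counts,
        [f"cell_{i}" for i in range(n_cells)],
        [f"gene_{j:04d}" for j in range(ng)],
        "counts",
    )
    return LabeledReference(expr, labels, type_names)


def marker_blocks(k: int, n_markers_per_type: int) -> dict[str, list[str]]:
    """Gene ids of each type's marker block under :func:`generate_reference`."""
    return {
        f"type_{t}": [
            f"gene_{j:04d}" for j in range(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        ]
        for t in range(k)
    }


def _domain_labels(rows: int, cols: int, k: int, layout: str) -> np.ndarray:
    """Partition a rows x cols grid into k contiguous domains."""
    if layout == "stripes":
        # k horizontal stripes of near-equal height
        edges = np.linspace(0, rows, k + 1)
        band = np.searchsorted(edges, np.arange(rows), side="right") - 1
        band = np.clip(band, 0, k - 1)
        return np.repeat(band, cols).reshape(rows, cols).ravel()
    if layout == "blocks":
        nb = math.ceil(math.sqrt(k))
        r_edges = np.linspace(0, rows, nb + 1)
        c_edges = np.linspace(0, cols, nb + 1)
        r_band = np.clip(np.searchsorted(r_edges, np.arange(rows), "right") - 1, 0, nb - 1)
        c_band = np.clip(np.searchsorted(c_edges, np.arange(cols), "right") - 1, 0, nb - 1)
        dom = (r_band[:, None] * nb + c_band[None, :]) % k
        return dom.ravel()
    raise ValueError(f"unknown domain layout: {layout!r}")


def simulate_spots(
    ref: LabeledReference,
    grid: tuple[int, int] = (20, 10),
    cells_per_spot: int | tuple[int, int] = 10,
    domain_layout: str = "stripes",
    purity: float = 5.0,
    seed: int = 0,
) -> SimulatedST:
    """Aggregate reference cells into pseudo-spots with known compositions.

    Parameters
    ----------
    ref
        Labeled single-cell counts to sample from (with replacement).
    grid
        ``(rows, cols)`` of the spot lattice; coordinates are grid indices.
    cells_per_spot
        Fixed count, or an inclusive ``(lo, hi)`` range sampled per spot.
    domain_layout
        ``"stripes"`` (horizontal bands) or ``"blocks"`` (checkered
        rectangles); one contiguous domain per cell type.
    purity
        Dirichlet concentration on the domain's dominant type (others get
        concentration 1). ``math.inf`` produces one-hot compositions.
    seed
        Seeds all sampling; identical seeds give bit-identical output.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    lo, hi = (cells_per_spot, cells_per_spot) if isinstance(cells_per_spot, int) else cells_per_spot
    if lo < 1 or hi < lo:
        raise ValueError("cells_per_spot must be >= 1 (and a valid range)")

    rng = np.random.default_rng(seed)
    k = ref.k
    n_spots = rows * cols
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=np.float64)
    domains = _domain_labels(rows, cols, k, domain_layout)

    cells_by_type = {
        t: np.flatnonzero(np.asarray(ref.labels) == t) for t in ref.type_names
    }

    X = np.zeros((n_spots, ref.expr.n_genes))
    P = np.zeros((n_spots, k))
    sampled: list[np.ndarray] = []
    for s in range(n_spots):
        n_cells = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        dom = int(domains[s])
        if math.isinf(purity):
            comp = np.zeros(k)
            comp[dom] = 1.0
        else:
            conc = np.ones(k)
            conc[dom] = purity
            comp = rng.dirichlet(conc)
        type_counts = rng.multinomial(n_cells, comp)
        chosen: list[np.ndarray] = []
        for t, c in zip(ref.type_names, type_counts):
            if c:
                chosen.append(rng.choice(cells_by_type[t], size=c, replace=True))
        cell_idx = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
        sampled.append(cell_idx)
        X[s] = ref.expr.values[cell_idx].sum(axis=0)
        P[s] = type_counts / n_cells

    expr = ExpressionMatrix(
        X, [f"spot_{s}" for s in range(n_spots)], list(ref.expr.gene_ids), "counts"
    )
    st = STDataset(expr, coords)
    provenance = {
        "seed": seed,
        "grid": (rows, cols),
        "cells_per_spot": (lo, hi),
        "domain_layout": domain_layout,
        "purity": purity,
        "domains": domains,
        "sampled_cells": sampled,
    }
    return SimulatedST(st=st, P=P, type_names=list(ref.type_names), provenance=provenance)


def write_simulated(sim: SimulatedST, path: str | Path) -> None:
    """Write as h5ad (P in obsm['proportions']) plus a proportions CSV fallback."""
    path = Path(path)
    adata = ad.AnnData(
        X=sim.st.expr.values,
        obs=pd.DataFrame(index=sim.st.expr.obs_ids),
        var=pd.DataFrame(index=sim.st.expr.gene_ids),
    )
    adata.obsm["spatial"] = sim.st.coords
    adata.obsm["proportions"] = sim.P
    adata.uns["type_names"] = list(sim.type_names)
    adata.write_h5ad(path)
    proportions_frame(sim).to_csv(path.with_suffix(".proportions.csv"))


def proportions_frame(sim: SimulatedST) -> pd.DataFrame:
    return pd.DataFrame(sim.P, index=sim.st.expr.obs_ids, columns=sim.type_names)


def read_simulated(path: str | Path) -> SimulatedST:
    """Read a simulated dataset written by :func:`write_simulated`."""
    adata = ad.read_h5ad(Path(path))
    if "proportions" not in adata.obsm:
        raise ValueError(f"{path}: no obsm['proportions'] ground truth")
    expr = ExpressionMatrix(
        np.asarray(adata.X, dtype=np.float64), list(adata.obs_names), list(adata.var_names)
    )
    st = STDataset(expr, np.asarray(adata.obsm["spatial"]))
    return SimulatedST(
        st=st,
        P=np.asarray(adata.obsm["proportions"]),
        type_names=list(adata.uns["type_names"]),
    )
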