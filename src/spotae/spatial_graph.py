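"""Spot KNN spatial graph with negative-exponential edge weights.

Each spot is linked to its k nearest neighbors in 2D space (default k=6,
the usual spot-adjacency count for hexagonal capture arrays). The directed
KNN relation is symmetrized with an elementwise max so every stated
neighbor edge is kept, and edge weights decay as exp(-d / d_bar) where
d_bar is the mean KNN-edge distance — dividing by d_bar keeps the weights
invariant to the coordinate units (pixels vs microns vs grid indices).

The unnormalized graph Laplacian L = D - W drives the regularizer
Tr(Z' L Z) = 0.5 * sum_ij W_ij ||z_i - z_j||^2, which penalizes latent
differences between spatial neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class SpatialGraph:
    """Symmetric weighted KNN graph over spots with its Laplacian."""

    W: sparse.csr_matrix
    D: sparse.csr_matrix
    L: sparse.csr_matrix

    @property
    def n(self) -> int:
        return self.W.shape[0]


def build_spatial_graph(coords: np.ndarray, k_neighbors: int = 6) -> SpatialGraph:
    """Build the symmetrized KNN graph with distance-decaying weights.

    Parameters
    ----------
    coords
        ``(n, 2)`` spot coordinates, used as given: Euclidean distances are
        unit-free after the mean-edge-distance normalization, and isotropy
        is preserved (no per-axis rescaling).
    k_neighbors
        Neighbors per spot (self excluded). Clipped to ``n - 1`` with a
        warning if it is too large. Ties in distance are broken by spot
        index, so the graph is deterministic.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must have shape (n, 2)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n:
        logger.warning("k_neighbors=%d >= n=%d; clipping to %d", k_neighbors, n, n - 1)
        k_neighbors = n - 1

    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    # stable argsort => ties broken by spot index
    nbr = np.argsort(dist, axis=1, kind="stable")[:, :k_neighbors]

    rows = np.repeat(np.arange(n), k_neighbors)
    cols = nbr.ravel()
    edge_d = dist[rows, cols]
    d_bar = edge_d.mean()
    weights = np.exp(-edge_d / d_bar) if d_bar > 0 else np.ones_like(edge_d)

    W = sparse.csr_matrix((weights, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)
    return SpatialGraph(W=W, D=_degree(W), L=laplacian(W))


def _degree(W: sparse.spmatrix) -> sparse.csr_matrix:
    deg = np.asarray(W.sum(axis=1)).ravel()
    return sparse.diags(deg, format="csr")


def laplacian(W) -> sparse.csr_matrix:
    """Unnormalized Laplacian L = D - W of a symmetric nonnegative weight matrix."""
    W = sparse.csr_matrix(W, dtype=np.float64)
    if W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    asym = abs(W - W.T)
    if asym.nnz and asym.max() > 1e-12:
        raise ValueError("W must be symmetric")
    if W.nnz and W.data.min() < 0:
        raise ValueError("W must be nonnegative")
    if np.abs(W.diagonal()).max(initial=0.0) > 0:
        raise ValueError("W must have a zero diagonal")
    return (_degree(W) - W).tocsr()


def laplacian_quadratic(Z: np.ndarray, L) -> float:
    """Tr(Z' L Z), the smoothness penalty of Z over the graph.

    Equals ``0.5 * sum_ij W_ij * ||z_i - z_j||^2`` for L = D - W.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != L.shape[0]:
        raise ValueError(f"Z has {Z.shape[0]} rows but L is {L.shape[0]}x{L.shape[1]}")
    return float(np.sum(Z * (L @ Z)))
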