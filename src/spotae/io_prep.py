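"""Containers and preprocessing for spot-level and single-cell expression data.

The deconvolution pipeline moves three kinds of objects around:

* :class:`ExpressionMatrix` — a dense observations x genes matrix with a
  ``layer_tag`` recording how far along the preprocessing chain it is
  (``counts`` -> ``normalized`` -> ``scaled``).
* :class:`STDataset` — an expression matrix paired with 2D spot coordinates.
* :class:`LabeledReference` — a single-cell count matrix with per-cell
  cell-type labels, used only to simulate training spots.

Preprocessing follows the common single-cell recipe: highly-variable-gene
selection on the reference counts (variance-stabilizing statistic), per-spot
library-size normalization to a fixed target, log1p, and per-gene scaling.
Scaling is applied after the simulated and real gene axes have been aligned,
so the network sees a single consistent feature scale.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

LayerTag = Literal["counts", "normalized", "scaled"]

#: Per-observation library-size target used by :func:`preprocess`.
LIBRARY_TARGET = 1e4


@dataclass
class ExpressionMatrix:
    """Dense observations x genes expression matrix.

    Parameters
    ----------
    values
        Array of shape ``(n_obs, n_genes)``.
    obs_ids
        Unique observation (spot or cell) identifiers.
    gene_ids
        Unique gene identifiers.
    layer_tag
        Which preprocessing stage the values are in.
    """

    values: np.ndarray
    obs_ids: list[str]
    gene_ids: list[str]
    layer_tag: LayerTag = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.obs_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.obs_ids)} obs ids and {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise ValueError("obs_ids must be unique")
        if self.layer_tag == "counts" and self.values.size and self.values.min() < 0:
            raise ValueError("counts layer must be nonnegative")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``gene_ids``, in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[:, cols].copy(), list(self.obs_ids), list(gene_ids), self.layer_tag
        )


@dataclass
class STDataset:
    """A spot x gene expression matrix with 2D spot coordinates."""

    expr: ExpressionMatrix
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n_spots, 2)")
        if self.coords.shape[0] != self.expr.n_obs:
            raise ValueError(
                f"coords rows ({self.coords.shape[0]}) != expression rows ({self.expr.n_obs})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_spots(self) -> int:
        return self.expr.n_obs


@dataclass
class LabeledReference:
    """Single-cell count matrix with per-cell cell-type labels."""

    expr: ExpressionMatrix
    labels: list[str]
    type_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.expr.n_obs:
            raise ValueError("one label per cell required")
        if not self.type_names:
            # preserve first-appearance order
            seen: dict[str, None] = {}
            for l in self.labels:
                seen.setdefault(l)
            self.type_names = list(seen)
        unknown = set(self.labels) - set(self.type_names)
        if unknown:
            raise ValueError(f"labels not in type_names: {sorted(unknown)}")
        counts = pd.Series(self.labels).value_counts()
        empty = [t for t in self.type_names if counts.get(t, 0) == 0]
        if empty:
            raise ValueError(f"cell types with zero cells: {empty}")

    @property
    def k(self) -> int:
        return len(self.type_names)


# ---------------------------------------------------------------------------
# highly variable genes (variance-stabilizing statistic)
# ---------------------------------------------------------------------------


def _vst_statistic(counts: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Per-gene standardized variance after a loess fit of log-variance on log-mean.

    Counts are clipped at ``mean + sqrt(N) * regularized_sd`` before the
    standardized variance is computed, which caps the influence of outlier
    cells on the ranking. Genes with zero variance get statistic 0.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n_cells = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(counts.shape[1])
    stat = np.zeros(counts.shape[1])
    usable = (var > 0) & (mean > 0)
    if not usable.any():
        return stat

    x = np.log10(mean[usable])
    y = np.log10(var[usable])
    if np.ptp(x) == 0:
        fitted = np.full(x.shape, y.mean())
    else:
        fitted = lowess(y, x, frac=span, return_sorted=False)
    reg_sd = np.sqrt(10.0 ** fitted)

    clip_val = mean[usable] + reg_sd * np.sqrt(n_cells)
    clipped = np.minimum(counts[:, usable], clip_val[None, :])
    sq_sum = np.square(clipped).sum(axis=0)
    lin_sum = clipped.sum(axis=0)
    mu = mean[usable]
    denom = (n_cells - 1) * reg_sd ** 2
    stat[usable] = (sq_sum - 2 * mu * lin_sum + n_cells * mu ** 2) / denom
    return stat


def select_hvg(ref: ExpressionMatrix, n_top: int = 5000) -> list[str]:
    """Rank genes by the variance-stabilizing statistic and return the top ``n_top``.

    Ties (including the all-zero genes, which score 0 and therefore rank
    last) are broken lexicographically by gene id so the result is invariant
    to row and column order.
    """
    if ref.layer_tag != "counts":
        raise ValueError("select_hvg expects a counts layer")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if ref.values.size == 0:
        raise ValueError("cannot select HVGs from an empty matrix")

    stat = _vst_statistic(ref.values)
    order = sorted(range(ref.n_genes), key=lambda j: (-stat[j], ref.gene_ids[j]))
    return [ref.gene_ids[j] for j in order[: min(n_top, ref.n_genes)]]


# ---------------------------------------------------------------------------
# normalization / scaling
# ---------------------------------------------------------------------------


def preprocess(
    expr: ExpressionMatrix,
    do_scale: bool = True,
    target_sum: float = LIBRARY_TARGET,
) -> ExpressionMatrix:
    """Library-size normalize to ``target_sum``, log1p, optionally scale per gene.

    Scaling centers each gene to mean 0 and unit variance (sample sd,
    ``ddof=1``); zero-variance genes are set to 0. Rows with zero total
    counts are left as zeros with a logged warning.
    """
    if expr.layer_tag != "counts":
        raise ValueError("preprocess expects a counts layer")
    X = expr.values.copy()
    row_sums = X.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        logger.warning("%d observation(s) have zero total counts; left as zeros", zero_rows.sum())
    safe = np.where(zero_rows, 1.0, row_sums)
    X = X / safe[:, None] * target_sum
    X[zero_rows] = 0.0
    X = np.log1p(X)

    tag: LayerTag = "normalized"
    if do_scale:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        X = X - mu[None, :]
        nz = sd > 0
        X[:, nz] /= sd[None, nz]
        X[:, ~nz] = 0.0
        tag = "scaled"
    return ExpressionMatrix(X, list(expr.obs_ids), list(expr.gene_ids), tag)


def align_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, sorted lexicographically."""
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValueError(
            "no shared genes between matrices "
            f"(first gene ids: {a.gene_ids[:3]} vs {b.gene_ids[:3]})"
        )
    return a.subset_genes(shared), b.subset_genes(shared)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

STFormat = Literal["h5ad", "mtx_dir", "csv"]


def _to_dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sparse.issparse(X) else X, dtype=np.float64)


def write_st(st: STDataset, path: str | Path, format: STFormat = "h5ad") -> None:
    """Write an :class:`STDataset` to disk.

    h5ad stores coordinates in ``obsm["spatial"]``; ``mtx_dir`` writes a
    directory with ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` +
    ``coords.tsv``; ``csv`` writes ``<path>.expr.csv`` and ``<path>.coords.csv``
    keyed by spot id.
    """
    path = Path(path)
    if format == "h5ad":
        adata = ad.AnnData(
            X=st.expr.values,
            obs=pd.DataFrame(index=st.expr.obs_ids),
            var=pd.DataFrame(index=st.expr.gene_ids),
        )
        adata.obsm["spatial"] = st.coords
        adata.uns["layer_tag"] = st.expr.layer_tag
        adata.write_h5ad(path)
    elif format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(st.expr.values))
        (path / "genes.tsv").write_text("\n".join(st.expr.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(st.expr.obs_ids) + "\n")
        coords = pd.DataFrame(st.coords, columns=["x", "y"], index=st.expr.obs_ids)
        coords.to_csv(path / "coords.tsv", sep="\t", header=True, index=True)
    elif format == "csv":
        expr = pd.DataFrame(st.expr.values, index=st.expr.obs_ids, columns=st.expr.gene_ids)
        expr.to_csv(_csv_expr_path(path))
        coords = pd.DataFrame(st.coords, columns=["x", "y"], index=st.expr.obs_ids)
        coords.to_csv(_csv_coords_path(path))
    else:
        raise ValueError(f"unknown format: {format!r}")


def _csv_expr_path(path: Path) -> Path:
    return path.with_suffix(".expr.csv")


def _csv_coords_path(path: Path) -> Path:
    return path.with_suffix(".coords.csv")


def read_st(path: str | Path, format: STFormat = "h5ad") -> STDataset:
    """Read an :class:`STDataset` written by :func:`write_st` (or compatible)."""
    path = Path(path)
    if format == "h5ad":
        adata = ad.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError(f"{path}: no obsm['spatial'] coordinates")
        tag = adata.uns.get("layer_tag", "counts")
        expr = ExpressionMatrix(
            _to_dense(adata.X), list(adata.obs_names), list(adata.var_names), tag
        )
        return STDataset(expr, np.asarray(adata.obsm["spatial"])[:, :2])
    if format == "mtx_dir":
        X = _to_dense(spio.mmread(path / "matrix.mtx"))
        gene_ids = (path / "genes.tsv").read_text().splitlines()
        barcodes_file = path / "barcodes.tsv"
        obs_ids = (
            barcodes_file.read_text().splitlines()
            if barcodes_file.exists()
            else [f"spot_{i}" for i in range(X.shape[0])]
        )
        coords_file = path / "coords.tsv"
        if not coords_file.exists():
            raise ValueError(f"{path}: coords.tsv is missing")
        coords = pd.read_csv(coords_file, sep="\t", index_col=0)
        if coords.shape[0] != X.shape[0]:
            raise ValueError(
                f"{path}: coords rows ({coords.shape[0]}) != matrix rows ({X.shape[0]})"
            )
        expr = ExpressionMatrix(X, obs_ids, gene_ids)
        return STDataset(expr, coords[["x", "y"]].to_numpy())
    if format == "csv":
        expr_df = pd.read_csv(_csv_expr_path(path), index_col=0)
        coords_df = pd.read_csv(_csv_coords_path(path), index_col=0)
        if list(expr_df.index.astype(str)) != list(coords_df.index.astype(str)):
            raise ValueError("spot ids in expression and coordinate CSVs do not match")
        expr = ExpressionMatrix(
            expr_df.to_numpy(dtype=np.float64),
            list(expr_df.index.astype(str)),
            list(expr_df.columns.astype(str)),
        )
        return STDataset(expr, coords_df[["x", "y"]].to_numpy())
    raise ValueError(f"unknown format: {format!r}")


def write_reference(ref: LabeledReference, path: str | Path) -> None:
    """Write a labeled reference as h5ad with labels in ``obs["cell_type"]``."""
    adata = ad.AnnData(
        X=ref.expr.values,
        obs=pd.DataFrame({"cell_type": ref.labels}, index=ref.expr.obs_ids),
        var=pd.DataFrame(index=ref.expr.gene_ids),
    )
    adata.uns["type_names"] = list(ref.type_names)
    adata.write_h5ad(Path(path))


def read_reference(path: str | Path, label_key: str = "cell_type") -> LabeledReference:
    """Read a labeled single-cell reference from h5ad."""
    adata = ad.read_h5ad(Path(path))
    if label_key not in adata.obs:
        raise ValueError(f"{path}: no obs[{label_key!r}] labels")
    expr = ExpressionMatrix(_to_dense(adata.X), list(adata.obs_names), list(adata.var_names))
    type_names = list(adata.uns.get("type_names", []))
    return LabeledReference(expr, list(adata.obs[label_key].astype(str)), type_names)
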