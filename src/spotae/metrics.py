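"""Evaluation statistics for deconvolution output.

Proportion-matrix agreement (predicted vs true spot compositions):

* PCC — per cell type, Pearson correlation across spots; reported as a
  vector plus mean +/- sd over types (higher is better).
* SSIM — per cell type, structural similarity between the predicted and
  true proportion fields rasterized to images (higher is better).
* JSD — per spot, Jensen-Shannon divergence between composition rows,
  natural log so the range is [0, ln 2] (lower is better).
* RMSE / Frobenius — entrywise error, pooled over the whole matrix; the
  two are related by frobenius = rmse * sqrt(ns * k) (lower is better).

Domain-label agreement: adjusted Rand index and cluster purity.

Spatial autocorrelation over a weighted neighbor graph: Moran's I (near +1
for smooth fields, negative for checkerboards) and Geary's C (below 1 for
positive autocorrelation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import gaussian_filter
from scipy.special import rel_entr
from sklearn.metrics import adjusted_rand_score

from .spatial_graph import SpatialGraph


@dataclass
class DeconvScore:
    """Bundle of proportion-agreement metrics for one predicted matrix."""

    per_type_pcc: np.ndarray
    pcc_mean: float
    pcc_sd: float
    ssim_per_type: np.ndarray | None
    jsd_mean: float
    rmse: float
    frobenius: float
    type_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "pcc_mean": self.pcc_mean,
            "pcc_sd": self.pcc_sd,
            "jsd_mean": self.jsd_mean,
            "rmse": self.rmse,
            "frobenius": self.frobenius,
            "per_type_pcc": [float(v) for v in self.per_type_pcc],
        }
        if self.ssim_per_type is not None:
            d["ssim_per_type"] = [float(v) for v in self.ssim_per_type]
            d["ssim_mean"] = float(np.mean(self.ssim_per_type))
        if self.type_names:
            d["type_names"] = list(self.type_names)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (metric, cell_type, value) table."""
        names = self.type_names or [str(t) for t in range(len(self.per_type_pcc))]
        rows = [("pcc", n, float(v)) for n, v in zip(names, self.per_type_pcc)]
        if self.ssim_per_type is not None:
            rows += [("ssim", n, float(v)) for n, v in zip(names, self.ssim_per_type)]
        rows += [
            ("pcc_mean", "", self.pcc_mean),
            ("pcc_sd", "", self.pcc_sd),
            ("jsd_mean", "", self.jsd_mean),
            ("rmse", "", self.rmse),
            ("frobenius", "", self.frobenius),
        ]
        return pd.DataFrame(rows, columns=["metric", "cell_type", "value"])


def _check_pair(P_hat, P_true) -> tuple[np.ndarray, np.ndarray]:
    P_hat = np.asarray(P_hat, dtype=np.float64)
    P_true = np.asarray(P_true, dtype=np.float64)
    if P_hat.shape != P_true.shape:
        raise ValueError(f"shape mismatch: {P_hat.shape} vs {P_true.shape}")
    return P_hat, P_true


def pcc_per_celltype(P_hat, P_true) -> tuple[np.ndarray, float, float]:
    """Per-type Pearson correlation across spots, plus mean and sd over types.

    A zero-variance column (on either side) scores 0 with a warning rather
    than NaN.
    """
    P_hat, P_true = _check_pair(P_hat, P_true)
    if P_hat.shape[0] < 2:
        raise ValueError("need at least 2 spots")
    a = P_hat - P_hat.mean(axis=0)
    b = P_true - P_true.mean(axis=0)
    sa = np.sqrt((a ** 2).sum(axis=0))
    sb = np.sqrt((b ** 2).sum(axis=0))
    ok = (sa > 0) & (sb > 0)
    if not ok.all():
        warnings.warn("zero-variance proportion column(s); PCC set to 0", stacklevel=2)
    pcc = np.zeros(P_hat.shape[1])
    pcc[ok] = (a[:, ok] * b[:, ok]).sum(axis=0) / (sa[ok] * sb[ok])
    return pcc, float(pcc.mean()), float(pcc.std(ddof=1)) if pcc.size > 1 else 0.0


def rmse(P_hat, P_true) -> float:
    """Root mean squared error pooled over all ns*k entries."""
    P_hat, P_true = _check_pair(P_hat, P_true)
    return float(np.sqrt(np.mean((P_hat - P_true) ** 2)))


def frobenius_distance(P_hat, P_true) -> float:
    """||P_hat - P_true||_F = sqrt(sum of squared entrywise differences)."""
    P_hat, P_true = _check_pair(P_hat, P_true)
    return float(np.linalg.norm(P_hat - P_true, "fro"))


def jsd_per_spot(P_hat, P_true, base: str = "e") -> tuple[np.ndarray, float]:
    """Per-spot Jensen-Shannon divergence between composition rows.

    ``JSD(p||q) = 0.5 KL(p||m) + 0.5 KL(q||m)`` with ``m = (p+q)/2`` and the
    convention ``0 log 0 = 0``. Natural log by default (range [0, ln 2]);
    ``base="2"`` rescales to [0, 1]. Rows off the simplex by more than 1e-6
    are renormalized with a warning.
    """
    P_hat, P_true = _check_pair(P_hat, P_true)

    def _simplex(M, name):
        if M.min() < 0:
            raise ValueError(f"{name} has negative entries")
        s = M.sum(axis=1)
        if np.abs(s - 1.0).max() > 1e-6:
            warnings.warn(f"{name} rows renormalized onto the simplex", stacklevel=3)
        return M / s[:, None]

    p = _simplex(P_hat, "P_hat")
    q = _simplex(P_true, "P_true")
    m = 0.5 * (p + q)
    jsd = 0.5 * rel_entr(p, m).sum(axis=1) + 0.5 * rel_entr(q, m).sum(axis=1)
    jsd = np.clip(jsd, 0.0, None)
    if base == "2":
        jsd = jsd / np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return jsd, float(jsd.mean())


# ---------------------------------------------------------------------------
# SSIM on rasterized proportion fields
# ---------------------------------------------------------------------------


def rasterize(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Place per-spot values on an integer lattice (nearest-point rounding).

    Lattice cells without a spot are 0. Raises if two spots collapse onto
    the same cell, which means the rounding is too coarse for these
    coordinates.
    """
    coords = np.asarray(coords, dtype=np.float64)
    ij = np.round(coords).astype(int)
    ij -= ij.min(axis=0)
    shape = ij.max(axis=0) + 1
    occupied = set()
    img = np.zeros(shape)
    for (i, j), v in zip(ij, values):
        if (i, j) in occupied:
            raise ValueError(
                "multiple spots collapse onto one raster cell; "
                "rescale coordinates to a finer lattice"
            )
        occupied.add((i, j))
        img[i, j] = v
    return img


def _ssim_image(a: np.ndarray, b: np.ndarray, sigma: float = 1.5) -> float:
    """Gaussian-weighted SSIM on data range 1 (C1=0.01^2, C2=0.03^2).

    The half-window border of the SSIM map is cropped before averaging
    (the standard convention); images smaller than the window fall back to
    the full-map mean.
    """
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    C1, C2 = 0.01 ** 2, 0.03 ** 2
    truncate = 3.5
    blur = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ua = gaussian_filter(a, **blur)
    ub = gaussian_filter(b, **blur)
    va = gaussian_filter(a * a, **blur) - ua * ua
    vb = gaussian_filter(b * b, **blur) - ub * ub
    cov = gaussian_filter(a * b, **blur) - ua * ub
    num = (2 * ua * ub + C1) * (2 * cov + C2)
    den = (ua ** 2 + ub ** 2 + C1) * (va + vb + C2)
    smap = num / den
    pad = int(truncate * sigma + 0.5)
    if min(smap.shape) > 2 * pad:
        smap = smap[pad:-pad, pad:-pad]
    return float(np.mean(smap))


def _minmax01(img: np.ndarray) -> np.ndarray:
    rng = img.max() - img.min()
    if rng == 0:
        return np.zeros_like(img)
    return (img - img.min()) / rng


def ssim_per_celltype(P_hat, P_true, coords, sigma: float = 1.5) -> np.ndarray:
    """Per-type SSIM between rasterized, min-max scaled proportion images."""
    P_hat, P_true = _check_pair(P_hat, P_true)
    out = np.empty(P_hat.shape[1])
    for t in range(P_hat.shape[1]):
        img_a = _minmax01(rasterize(P_hat[:, t], coords))
        img_b = _minmax01(rasterize(P_true[:, t], coords))
        out[t] = _ssim_image(img_a, img_b, sigma=sigma)
    return out


# ---------------------------------------------------------------------------
# clustering agreement
# ---------------------------------------------------------------------------


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (pair-counting, chance-corrected)."""
    labels_a, labels_b = list(labels_a), list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    if not labels_a:
        raise ValueError("empty labelings")
    return float(adjusted_rand_score(labels_a, labels_b))


def purity(clusters, truth) -> float:
    """Fraction of points whose cluster's majority truth label matches them."""
    clusters, truth = list(clusters), list(truth)
    if len(clusters) != len(truth):
        raise ValueError("label sequences differ in length")
    if not clusters:
        raise ValueError("empty labelings")
    tab = pd.crosstab(pd.Series(clusters), pd.Series(truth))
    return float(tab.max(axis=1).sum() / len(clusters))


# ---------------------------------------------------------------------------
# spatial autocorrelation
# ---------------------------------------------------------------------------


def _weights_of(graph) -> sparse.csr_matrix:
    W = graph.W if isinstance(graph, SpatialGraph) else sparse.csr_matrix(graph)
    if W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    return W


def _autocorr_inputs(values, graph):
    W = _weights_of(graph)
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size != W.shape[0]:
        raise ValueError("values length must equal the number of spots")
    if x.size < 2:
        raise ValueError("need at least 2 spots")
    S0 = W.sum()
    if S0 == 0:
        raise ValueError("graph has zero total edge weight")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("spatial autocorrelation undefined for constant values")
    return W, x, z, S0, denom


def morans_i(values, graph) -> float:
    """Moran's I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2)."""
    W, _, z, S0, denom = _autocorr_inputs(values, graph)
    n = z.size
    return float((n / S0) * (z @ (W @ z)) / denom)


def gearys_c(values, graph) -> float:
    """Geary's C = ((n-1) / 2 S0) * (sum_ij w_ij (x_i - x_j)^2) / (sum_i z_i^2)."""
    W, x, z, S0, denom = _autocorr_inputs(values, graph)
    n = x.size
    deg = np.asarray(W.sum(axis=1)).ravel()
    # sum_ij w_ij (x_i - x_j)^2 = 2 x' L x for symmetric W
    quad = float(x @ (deg * x) - x @ (W @ x))
    return float(((n - 1) / (2.0 * S0)) * 2.0 * quad / denom)


# ---------------------------------------------------------------------------
# one-call evaluation
# ---------------------------------------------------------------------------


def evaluate(
    P_hat,
    P_true,
    coords=None,
    type_names: list[str] | None = None,
) -> DeconvScore:
    """Compute the full proportion-agreement score bundle.

    SSIM is included only when spot coordinates are supplied (it needs a
    spatial raster).
    """
    P_hat, P_true = _check_pair(P_hat, P_true)
    pcc, pcc_mean, pcc_sd = pcc_per_celltype(P_hat, P_true)
    _, jsd_mean = jsd_per_spot(P_hat, P_true)
    ssim = ssim_per_celltype(P_hat, P_true, coords) if coords is not None else None
    return DeconvScore(
        per_type_pcc=pcc,
        pcc_mean=pcc_mean,
        pcc_sd=pcc_sd,
        ssim_per_type=ssim,
        jsd_mean=jsd_mean,
        rmse=rmse(P_hat, P_true),
        frobenius=frobenius_distance(P_hat, P_true),
        type_names=type_names or [],
    )
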