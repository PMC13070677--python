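"""Spatially regularized autoencoder for spot deconvolution.

The model factors spot expression through a latent code with one dimension
per cell type:

* encoder ``psi``: an MLP (default ng -> 512 -> 128 -> k) with ELU hidden
  activations and a softplus output, so the latent code Z is nonnegative and
  row-normalizes into valid proportions without clipping;
* decoder ``phi``: a single bias-free linear map k -> ng, so its k x ng
  weight matrix is directly the cell-type-by-gene signature — decoding a
  one-hot latent vector returns exactly one signature row.

Training is in two stages over a shared parameter set:

* stage 1 on simulated spots with known proportions P minimizes
  ``mean|X_s - X_hat| + mean|P - Z| + alpha * Tr(Z' L Z) / ns`` — an
  entrywise L1 reconstruction (L1 preserves the sparsity of spot
  expression), direct supervision of the latent code by the known
  compositions, and a graph smoothness penalty;
* stage 2 drops the supervision term and continues on the target data with
  ``mean|X_r - X_hat| + alpha * Tr(Z' L Z) / ns``, adapting the same network
  to the data being deconvolved.

Each L1 term is the *mean* absolute deviation over its entries and the
Laplacian trace is averaged per spot. Averaging keeps the three terms on
comparable scales regardless of the gene count: with raw entrywise sums the
reconstruction term (ns*ng entries) grows ~ng/k times faster than the
supervision term (ns*k entries) and simply drowns it, and the latent code
never aligns with the cell-type axes.

Both stages run full-batch Adam: the Laplacian term couples every spot, so
mini-batching would require subgraph Laplacians, and spot counts are small
enough (thousands) that exactness is cheap. The whole model is plain numpy
with hand-derived gradients; all randomness flows through one seeded
generator, so CPU runs are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_prep import STDataset
from .simulate import SimulatedST
from .spatial_graph import SpatialGraph, laplacian_quadratic

logger = logging.getLogger(__name__)

CHECKPOINT_SCHEMA = 1


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``alpha`` weighs the spatial smoothness penalty (0.1 trades off spatial
    against transcriptional information well; large values let spatial
    information dominate and degrade the code). ``lr`` is the Adam step
    size. Epoch counts are full-batch passes; training stops early when the
    objective has been flat (relative change < ``plateau_tol``) over
    ``plateau_window`` epochs.
    """

    alpha: float = 0.1
    lr: float = 1e-4
    epochs_stage1: int = 4000
    epochs_stage2: int = 2000
    k_neighbors: int = 6
    hidden_dims: tuple[int, ...] = (512, 128)
    seed: int = 0
    device: str = "cpu"
    plateau_window: int = 200
    plateau_tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)


@dataclass
class DeconvResult:
    """Row-normalized proportions plus the decoder-derived signatures."""

    proportions: np.ndarray
    signatures: np.ndarray
    spot_ids: list[str]
    type_names: list[str]
    gene_ids: list[str]
    loss_trace: list[float] = field(default_factory=list)
    config: TrainConfig | None = None

    def proportions_frame(self):
        import pandas as pd

        return pd.DataFrame(self.proportions, index=self.spot_ids, columns=self.type_names)

    def signatures_frame(self):
        import pandas as pd

        return pd.DataFrame(self.signatures, index=self.type_names, columns=self.gene_ids)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _softplus(x: np.ndarray) -> np.ndarray:
    # stable: log(1 + e^x) = max(x, 0) + log1p(e^-|x|)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SpotAutoencoder:
    """Encoder/decoder parameter container with hand-derived gradients."""

    def __init__(
        self,
        ng: int,
        type_names: Sequence[str],
        hidden_dims: Sequence[int] = (512, 128),
        seed: int = 0,
        gene_ids: Sequence[str] | None = None,
    ):
        self.ng = int(ng)
        self.type_names = [str(t) for t in type_names]
        self.k = len(self.type_names)
        self.hidden_dims = tuple(int(h) for h in hidden_dims)
        self.gene_ids = list(gene_ids) if gene_ids is not None else None
        if self.k < 1 or self.ng < 1:
            raise ValueError("need at least one cell type and one gene")
        rng = np.random.default_rng(seed)
        dims = (self.ng, *self.hidden_dims, self.k)
        # fan-in uniform init, U(-1/sqrt(fan_in), 1/sqrt(fan_in))
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(d_in)
            self.weights.append(rng.uniform(-bound, bound, size=(d_in, d_out)))
            self.biases.append(rng.uniform(-bound, bound, size=d_out))
        bound = 1.0 / np.sqrt(self.k)
        self.decoder_weight = rng.uniform(-bound, bound, size=(self.k, self.ng))

    # -- forward ----------------------------------------------------------

    def _encode_cached(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.ng:
            raise ValueError(f"expected input with {self.ng} genes, got shape {X.shape}")
        pre_acts: list[np.ndarray] = []
        h = X
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            pre = h @ self.weights[i] + self.biases[i]
            pre_acts.append(pre)
            h = _elu(pre)
        pre = h @ self.weights[-1] + self.biases[-1]
        pre_acts.append(pre)
        return _softplus(pre), pre_acts

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent code Z = psi(X); nonnegative via the softplus output."""
        return self._encode_cached(X)[0]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Reconstruction X_hat = phi(Z) = Z @ decoder_weight."""
        Z = np.asarray(Z, dtype=np.float64)
        if Z.ndim != 2 or Z.shape[1] != self.k:
            raise ValueError(f"expected latent width {self.k}, got shape {Z.shape}")
        return Z @ self.decoder_weight

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, self.decoder_weight]

    # -- backward ---------------------------------------------------------

    def _gradients(
        self,
        X: np.ndarray,
        P: np.ndarray | None,
        L,
        alpha: float,
    ) -> tuple[float, list[np.ndarray], dict[str, float]]:
        """Loss and parameter gradients for one full-batch step.

        Subgradient of the mean absolute deviation taken as sign(.)/size;
        the Laplacian term contributes 2 * alpha * L @ Z / ns to dL/dZ
        (L symmetric).
        """
        Z, pre_acts = self._encode_cached(X)
        X_hat = Z @ self.decoder_weight
        ns = X.shape[0]

        resid = X - X_hat
        recon = float(np.abs(resid).mean())
        smooth = laplacian_quadratic(Z, L) / ns if alpha > 0 else 0.0
        superv = float(np.abs(P - Z).mean()) if P is not None else 0.0
        loss = recon + superv + alpha * smooth
        terms = {"reconstruction": recon, "supervision": superv, "smoothness": alpha * smooth}

        d_Xhat = -np.sign(resid) / resid.size
        g_dec = Z.T @ d_Xhat
        dZ = d_Xhat @ self.decoder_weight.T
        if P is not None:
            dZ += -np.sign(P - Z) / Z.size
        if alpha > 0:
            dZ += (2.0 * alpha / ns) * (L @ Z)

        g_w: list[np.ndarray] = [np.empty(0)] * len(self.weights)
        g_b: list[np.ndarray] = [np.empty(0)] * len(self.biases)
        d_pre = dZ * _sigmoid(pre_acts[-1])
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden, -1, -1):
            h_in = X if i == 0 else _elu(pre_acts[i - 1])
            g_w[i] = h_in.T @ d_pre
            g_b[i] = d_pre.sum(axis=0)
            if i > 0:
                d_pre = (d_pre @ self.weights[i].T) * _elu_grad(pre_acts[i - 1])
        return loss, [*g_w, *g_b, g_dec], terms

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path, config: TrainConfig | None = None) -> None:
        """Write a single-file checkpoint (npz) with parameters and metadata."""
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "ng": self.ng,
            "k": self.k,
            "hidden_dims": list(self.hidden_dims),
            "type_names": self.type_names,
            "gene_ids": self.gene_ids,
            "config": asdict(config) if config else None,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        arrays["decoder_weight"] = self.decoder_weight
        np.savez(Path(path), meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["SpotAutoencoder", TrainConfig | None]:
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
            model = cls(
                ng=meta["ng"],
                type_names=meta["type_names"],
                hidden_dims=meta["hidden_dims"],
                gene_ids=meta["gene_ids"],
            )
            model.weights = [data[f"w{i}"] for i in range(len(model.weights))]
            model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
            model.decoder_weight = data["decoder_weight"]
        cfg = TrainConfig(**{**meta["config"], "hidden_dims": tuple(meta["config"]["hidden_dims"])}) if meta["config"] else None
        return model, cfg


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


def _check_loss_inputs(X, X_hat, Z, L, alpha) -> None:
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if X.shape != X_hat.shape:
        raise ValueError(f"X {X.shape} and X_hat {X_hat.shape} differ in shape")
    if Z.shape[0] != X.shape[0] or Z.shape[0] != L.shape[0]:
        raise ValueError("Z rows must match X rows and the Laplacian dimension")


def supervision_term(P, Z) -> float:
    """``mean|P - Z|`` — the latent supervision term of the stage-1 objective."""
    P, Z = np.asarray(P, dtype=np.float64), np.asarray(Z, dtype=np.float64)
    if P.shape != Z.shape:
        raise ValueError(f"P {P.shape} and Z {Z.shape} differ in shape")
    return float(np.abs(P - Z).mean())


def loss_supervised(X_s, X_hat, P, Z, L, alpha: float) -> float:
    """``mean|X_s - X_hat| + mean|P - Z| + alpha * Tr(Z' L Z) / ns``.

    The L1 terms are mean absolute deviations and the Laplacian trace is
    averaged per spot, so the three terms stay on comparable scales
    whatever the gene count (see the module docstring).
    """
    # built as unsupervised + supervision so the decomposition
    # loss_supervised = loss_unsupervised + supervision_term is exact
    return loss_unsupervised(X_s, X_hat, Z, L, alpha) + supervision_term(P, Z)


def loss_unsupervised(X_r, X_hat, Z, L, alpha: float) -> float:
    """``mean|X_r - X_hat| + alpha * Tr(Z' L Z) / ns`` — supervision-free objective."""
    X_r, X_hat, Z = (np.asarray(a, dtype=np.float64) for a in (X_r, X_hat, Z))
    _check_loss_inputs(X_r, X_hat, Z, L, alpha)
    return (
        float(np.abs(X_r - X_hat).mean())
        + alpha * laplacian_quadratic(Z, L) / X_r.shape[0]
    )


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _train(
    model: SpotAutoencoder,
    X: np.ndarray,
    P: np.ndarray | None,
    graph: SpatialGraph,
    cfg: TrainConfig,
    epochs: int,
    stage: str,
) -> list[float]:
    if graph.n != X.shape[0]:
        raise ValueError(f"graph has {graph.n} nodes but X has {X.shape[0]} rows")
    params = model.parameters()
    opt = _Adam(params, lr=cfg.lr)
    trace: list[float] = []
    for epoch in range(epochs):
        loss, grads, terms = model._gradients(X, P, graph.L, cfg.alpha)
        if not np.isfinite(loss):
            bad = {k: v for k, v in terms.items() if not np.isfinite(v)}
            raise FloatingPointError(
                f"{stage}: non-finite loss at epoch {epoch}; offending term(s): {bad or terms}"
            )
        opt.step(params, grads)
        trace.append(loss)
        w = cfg.plateau_window
        if epoch >= w and trace[-w - 1] != 0:
            rel = abs(trace[-w - 1] - trace[-1]) / abs(trace[-w - 1])
            if rel < cfg.plateau_tol:
                logger.info("%s: loss plateau at epoch %d; stopping early", stage, epoch)
                break
    return trace


def fit_stage1(
    model: SpotAutoencoder,
    sim: SimulatedST,
    graph: SpatialGraph,
    cfg: TrainConfig,
) -> tuple[SpotAutoencoder, list[float]]:
    """Supervised stage: train on simulated spots with known proportions.

    ``sim.st.expr`` is expected to be preprocessed (normalized/log/scaled)
    and ``graph`` built on the simulated coordinates.
    """
    X = sim.st.expr.values
    if model.gene_ids is None:
        model.gene_ids = list(sim.st.expr.gene_ids)
    elif model.gene_ids != list(sim.st.expr.gene_ids):
        raise ValueError("simulated data gene axis does not match the model's gene list")
    trace = _train(model, X, sim.P, graph, cfg, cfg.epochs_stage1, "stage1")
    return model, trace


def fit_stage2(
    model: SpotAutoencoder,
    real: STDataset,
    graph: SpatialGraph,
    cfg: TrainConfig,
) -> tuple[SpotAutoencoder, list[float]]:
    """Reconstruction-only stage: adapt the trained model to the target data.

    The target expression must be aligned to the stage-1 gene axis.
    ``epochs_stage2 = 0`` leaves the model untouched.
    """
    if model.gene_ids is not None and model.gene_ids != list(real.expr.gene_ids):
        raise ValueError("target data gene axis does not match the stage-1 gene list")
    if cfg.epochs_stage2 == 0:
        return model, []
    trace = _train(model, real.expr.values, None, graph, cfg, cfg.epochs_stage2, "stage2")
    return model, trace


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


def row_normalize(Z: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; all-zero rows become uniform 1/k."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.min() < 0:
        raise ValueError("row_normalize expects nonnegative input")
    sums = Z.sum(axis=1)
    zero = sums == 0
    out = np.empty_like(Z)
    out[~zero] = Z[~zero] / sums[~zero, None]
    out[zero] = 1.0 / Z.shape[1]
    return out


def extract_signatures(model: SpotAutoencoder) -> np.ndarray:
    """The k x ng cell-type-by-gene signature: the decoder's linear weights.

    Row t is the image of the latent basis vector e_t under the (bias-free)
    decoder, i.e. the expression profile the model attributes to type t.
    """
    return model.decoder_weight.copy()


def deconvolve(
    model: SpotAutoencoder,
    st: STDataset,
    loss_trace: list[float] | None = None,
    config: TrainConfig | None = None,
) -> DeconvResult:
    """Encode, row-normalize onto the simplex, and attach signatures."""
    Z = model.encode(st.expr.values)
    return DeconvResult(
        proportions=row_normalize(Z),
        signatures=extract_signatures(model),
        spot_ids=list(st.expr.obs_ids),
        type_names=list(model.type_names),
        gene_ids=list(st.expr.gene_ids),
        loss_trace=list(loss_trace or []),
        config=config,
    )
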