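"""Deep-embedded clustering objective, spatial regularizer and training loop.

The model is trained in two stages, full batch, with Adam (lr 0.01):

1. *Pretraining* (200 epochs): reconstruction loss plus the spatial
   regularizer — everything except the clustering term.
2. *Clustering stage* (200 epochs): k-means (K=10 centroids, 10 restarts)
   initializes cluster centroids on the joint embedding; then the combined
   objective

       L = Loss_rec + lambda * Loss_clu + gamma * Loss_spa

   is minimized, with lambda=0.1 and gamma=1 by default. Loss_clu is the
   KL divergence KL(T || Q) between the Student-t soft assignment Q of spots
   to centroids and the sharpened target distribution T, recomputed once per
   epoch from the current Q. Centroids are free parameters updated by the
   optimizer alongside the network weights.

Loss_spa pulls the pairwise embedding-distance structure toward the pairwise
spatial-distance structure: with both distance matrices min-max normalized to
[0, 1], it averages D^(s)_ij * (1 - D^(h)_ij) over all ordered spot pairs, so
spatially distant pairs are pushed apart in embedding space. The exact form
costs O(N^2); it is evaluated in row chunks, and beyond
``SPATIAL_EXACT_LIMIT`` spots an unbiased Monte-Carlo estimate over sampled
pairs is used per step instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

from .autodiff import Tensor
from .exceptions import ConfigError, NumericalError
from .model import EmbeddingSet, ModelParams, forward_pass
from .utils import stage_seed

__all__ = [
    "TrainConfig",
    "ClusterState",
    "LossTrace",
    "soft_assignment",
    "target_distribution",
    "dec_loss",
    "spatial_regularization",
    "total_loss",
    "kmeans_init",
    "Adam",
    "pretrain",
    "fit",
]

SPATIAL_EXACT_LIMIT = 8000  # above this many spots, sample pairs per step
SPATIAL_SAMPLE_PAIRS = 2048
_EPS = 1e-12


@dataclass
class TrainConfig:
    """All hyperparameters of the method, with the defaults used throughout.

    ``lam`` weights the clustering loss, ``gamma`` the spatial regularizer;
    either can be zeroed to obtain the two ablated variants of the objective.
    """

    k: int = 20
    lam: float = 0.1
    gamma: float = 1.0
    lr: float = 0.01
    pretrain_epochs: int = 200
    train_epochs: int = 200
    d_f: int = 20
    d_g: int = 8
    hidden_f: int = 100
    hidden_g: int = 32
    n_centroids: int = 10
    pca_components: int = 200
    min_spots: int = 5
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.lam < 0 or self.gamma < 0:
            raise ConfigError("lam and gamma must be non-negative")
        if self.lr < 0:
            raise ConfigError("lr must be non-negative")
        if self.pretrain_epochs < 1 or self.train_epochs < 1:
            raise ConfigError("epoch counts must be >= 1")
        if min(self.k, self.d_f, self.d_g, self.hidden_f, self.hidden_g, self.n_centroids) < 1:
            raise ConfigError("dimensions, k and n_centroids must be positive")


@dataclass
class ClusterState:
    """Centroids, soft assignment and target distribution at the end of training."""

    centroids: np.ndarray
    Q: np.ndarray
    T: np.ndarray

    @property
    def hard_labels(self) -> np.ndarray:
        return self.Q.argmax(axis=1)


@dataclass
class LossTrace:
    """Per-epoch loss components."""

    rec: list[float] = field(default_factory=list)
    clu: list[float] = field(default_factory=list)
    spa: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)

    def append(self, rec: float, clu: float, spa: float, total: float) -> None:
        self.rec.append(rec)
        self.clu.append(clu)
        self.spa.append(spa)
        self.total.append(total)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.total) + 1),
                "loss_rec": self.rec,
                "loss_clu": self.clu,
                "loss_spa": self.spa,
                "loss_total": self.total,
            }
        )


# --------------------------------------------------------------------------
# DEC algebra (numpy reference forms)
# --------------------------------------------------------------------------

def soft_assignment(H: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Student-t (1 dof) soft assignment of each spot to each centroid.

    q_ik = (1 + ||h_i - mu_k||^2)^-1, normalized over k.
    """
    H = np.asarray(H, dtype=np.float64)
    centroids = np.asarray(centroids, dtype=np.float64)
    if centroids.shape[0] < 2:
        raise ConfigError("need at least 2 centroids")
    d2 = cdist(H, centroids, metric="sqeuclidean")
    q = 1.0 / (1.0 + d2)
    return q / q.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened target: t_ik = (q_ik^2 / f_k) / sum_k' (q_ik'^2 / f_k'), f_k = sum_i q_ik."""
    Q = np.asarray(Q, dtype=np.float64)
    f = Q.sum(axis=0)
    w = Q**2 / np.maximum(f, _EPS)
    return w / w.sum(axis=1, keepdims=True)


def dec_loss(T: np.ndarray, Q: np.ndarray) -> float:
    """KL(T || Q) = sum_i sum_k t_ik log(t_ik / q_ik); >= 0, zero iff T == Q."""
    T = np.asarray(T, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if T.shape != Q.shape:
        raise ConfigError("T and Q must have identical shapes")
    Qs = np.maximum(Q, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(T > 0, T * np.log(T / Qs), 0.0)
    return float(terms.sum())


# --------------------------------------------------------------------------
# Spatial regularization (numpy reference forms)
# --------------------------------------------------------------------------

def _minmax_pairwise(X: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances min-max normalized to [0, 1].

    The diagonal makes the minimum 0, so this is division by the maximum;
    a zero-range (all-identical) matrix normalizes to all-zeros.
    """
    D = cdist(X, X)
    m = D.max()
    return D / m if m > 0 else np.zeros_like(D)


def spatial_regularization(
    S: np.ndarray,
    H: np.ndarray,
    mode: str = "exact",
    chunk: int = 1024,
    n_pairs: int = SPATIAL_SAMPLE_PAIRS,
    seed: int | None = None,
) -> float:
    """Mean over all N^2 ordered pairs of D^(s)_ij * (1 - D^(h)_ij).

    ``mode="exact"`` accumulates the double sum in row chunks;
    ``mode="sampled"`` returns an unbiased Monte-Carlo estimate over
    ``n_pairs`` uniformly drawn ordered pairs (normalization maxima are still
    computed exactly).
    """
    S = np.asarray(S, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    n = S.shape[0]
    if n < 2:
        raise ConfigError("need at least 2 spots")
    if H.shape[0] != n:
        raise ConfigError("S and H must have the same number of rows")
    if not np.all(np.isfinite(H)):
        raise NumericalError("non-finite embedding in spatial regularization")

    # pass 1: normalization maxima (chunked)
    max_s = max_h = 0.0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        max_s = max(max_s, cdist(S[lo:hi], S).max())
        max_h = max(max_h, cdist(H[lo:hi], H).max())
    if max_s == 0.0:
        return 0.0

    if mode == "sampled":
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=n_pairs)
        j = rng.integers(0, n, size=n_pairs)
        ds = np.linalg.norm(S[i] - S[j], axis=1) / max_s
        dh = np.linalg.norm(H[i] - H[j], axis=1)
        dh = dh / max_h if max_h > 0 else np.zeros_like(dh)
        return float((ds * (1.0 - dh)).mean())
    if mode != "exact":
        raise ConfigError(f"unknown mode {mode!r}")

    total = 0.0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        ds = cdist(S[lo:hi], S) / max_s
        dh = cdist(H[lo:hi], H)
        dh = dh / max_h if max_h > 0 else np.zeros_like(dh)
        total += float((ds * (1.0 - dh)).sum())
    return total / n**2


def total_loss(loss_rec: float, loss_clu: float, loss_spa: float, cfg: TrainConfig) -> float:
    """L = Loss_rec + lambda * Loss_clu + gamma * Loss_spa."""
    return float(loss_rec) + cfg.lam * float(loss_clu) + cfg.gamma * float(loss_spa)


# --------------------------------------------------------------------------
# Differentiable (Tensor) counterparts used inside the loop
# --------------------------------------------------------------------------

def _soft_assignment_t(H: Tensor, centroids: Tensor) -> Tensor:
    hh = (H * H).sum(axis=1, keepdims=True)  # (N,1)
    cc = (centroids * centroids).sum(axis=1, keepdims=True).T  # (1,K)
    d2 = hh + cc - 2.0 * (H @ centroids.T)
    q = (d2 + 1.0) ** -1.0
    return q / q.sum(axis=1, keepdims=True)


def _dec_loss_t(T: np.ndarray, Q: Tensor) -> Tensor:
    logQ = (Q + _EPS).log()
    const = float(np.sum(np.where(T > 0, T * np.log(np.maximum(T, _EPS)), 0.0)))
    return const - (Tensor(T) * logQ).sum(axis=None)


def _pairwise_dist_t(H: Tensor) -> Tensor:
    hh = (H * H).sum(axis=1, keepdims=True)
    d2 = hh + hh.T - 2.0 * (H @ H.T)
    # tiny floor keeps sqrt differentiable at the zero diagonal
    return (d2.relu() + 1e-30).sqrt()


def _spatial_reg_t(
    ctx: dict,
    H: Tensor,
    rng: np.random.Generator | None = None,
    n_pairs: int = SPATIAL_SAMPLE_PAIRS,
) -> Tensor:
    """Differentiable Loss_spa.

    ``ctx`` comes from :func:`_precompute_ds`: either the dense pre-normalized
    spatial distance matrix (exact mode, N <= SPATIAL_EXACT_LIMIT) or the raw
    coordinates plus their exact distance maximum (Monte-Carlo mode over
    ``n_pairs`` sampled ordered pairs).
    """
    n = H.shape[0]
    if "Ds_norm" in ctx:
        Ds_norm = ctx["Ds_norm"]
        Dh = _pairwise_dist_t(H)
        mx = Dh.max()
        if mx.data <= 0:
            return Tensor(float(Ds_norm.mean()))
        return (Tensor(Ds_norm) * (1.0 - Dh / mx)).mean(axis=None)
    assert rng is not None
    S, max_s = ctx["S"], ctx["max_s"]
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    ds = np.linalg.norm(S[i] - S[j], axis=1) / max_s
    diff = H.take_rows(i) - H.take_rows(j)
    dh = ((diff * diff).sum(axis=1) + 1e-30).sqrt()
    mx = dh.max()
    if mx.data <= 0:
        return Tensor(float(ds.mean()))
    return (Tensor(ds) * (1.0 - dh / mx)).mean(axis=None)


# --------------------------------------------------------------------------
# Optimizer
# --------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# --------------------------------------------------------------------------
# Training stages
# --------------------------------------------------------------------------

def _check_finite(value: float, epoch: int, stage: str) -> None:
    if not np.isfinite(value):
        raise NumericalError(f"{stage} loss diverged (non-finite) at epoch {epoch}")


def _precompute_ds(S: np.ndarray, n: int, chunk: int = 2048) -> dict:
    """Spatial-distance context for Loss_spa (dense matrix or sampling info)."""
    S = np.asarray(S, dtype=np.float64)
    if n <= SPATIAL_EXACT_LIMIT:
        return {"Ds_norm": _minmax_pairwise(S)}
    max_s = 0.0
    for lo in range(0, n, chunk):
        max_s = max(max_s, cdist(S[lo : lo + chunk], S).max())
    return {"S": S, "max_s": max(max_s, _EPS)}


def pretrain(
    params: ModelParams,
    X: np.ndarray,
    A: sparse.spmatrix,
    S: np.ndarray,
    cfg: TrainConfig,
) -> LossTrace:
    """Stage 1: minimize Loss_rec + gamma * Loss_spa (no clustering term)."""
    X = np.asarray(X, dtype=np.float64)
    opt = Adam(params.trainable(), lr=cfg.lr)
    rng = np.random.default_rng(stage_seed(cfg.seed, "pretrain"))
    Ds = _precompute_ds(S, X.shape[0]) if cfg.gamma > 0 else None
    trace = LossTrace()
    for epoch in range(1, cfg.pretrain_epochs + 1):
        opt.zero_grad()
        eps = rng.standard_normal((X.shape[0], cfg.d_g))
        out = forward_pass(params, X, A, sample=True, eps=eps)
        loss = out["loss_rec"]
        spa_val = 0.0
        if cfg.gamma > 0:
            spa = _spatial_reg_t(Ds, out["H"], rng=rng)
            spa_val = float(spa.data)
            loss = loss + cfg.gamma * spa
        _check_finite(float(loss.data), epoch, "pretrain")
        loss.backward()
        opt.step()
        trace.append(float(out["loss_rec"].data), 0.0, spa_val, float(loss.data))
    return trace


def kmeans_init(H: np.ndarray, n_centroids: int, seed: int, n_init: int = 10) -> np.ndarray:
    """Seeded k-means centroids on the joint embedding (best of ``n_init`` restarts)."""
    from sklearn.cluster import KMeans

    if n_centroids > H.shape[0]:
        raise ConfigError(
            f"more centroids than spots: K={n_centroids} > N={H.shape[0]}"
        )
    km = KMeans(n_clusters=n_centroids, n_init=n_init, random_state=seed)
    km.fit(H)
    return km.cluster_centers_.astype(np.float64)


def fit(
    params: ModelParams,
    X: np.ndarray,
    A: sparse.spmatrix,
    S: np.ndarray,
    cfg: TrainConfig,
) -> tuple[EmbeddingSet, ClusterState, LossTrace]:
    """Stage 2: joint optimization of reconstruction, clustering and spatial terms.

    Centroids are initialized by k-means on the (mean-mode) joint embedding and
    then trained as free parameters. The target distribution T is recomputed
    once per epoch from the current soft assignment. The returned embedding
    uses the mean of the spatial encoder (no sampling).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    H0 = forward_pass(params, X, A, sample=False)["H"].data
    centroids = Tensor(
        kmeans_init(H0, cfg.n_centroids, stage_seed(cfg.seed, "kmeans")),
        requires_grad=True,
    )
    opt = Adam(params.trainable() + [centroids], lr=cfg.lr)
    rng = np.random.default_rng(stage_seed(cfg.seed, "fit"))
    Ds = _precompute_ds(S, n) if cfg.gamma > 0 else None
    trace = LossTrace()
    for epoch in range(1, cfg.train_epochs + 1):
        opt.zero_grad()
        eps = rng.standard_normal((n, cfg.d_g))
        out = forward_pass(params, X, A, sample=True, eps=eps)
        Q_t = _soft_assignment_t(out["H"], centroids)
        T = target_distribution(Q_t.data)
        # KL(T||Q) averaged per spot ("batchmean"): keeps the lambda weight
        # meaningful across dataset sizes; dec_loss() reports the raw sum.
        clu = _dec_loss_t(T, Q_t) * (1.0 / n)
        loss = out["loss_rec"] + cfg.lam * clu
        spa_val = 0.0
        if cfg.gamma > 0:
            spa = _spatial_reg_t(Ds, out["H"], rng=rng)
            spa_val = float(spa.data)
            loss = loss + cfg.gamma * spa
        _check_finite(float(loss.data), epoch, "clustering-stage")
        loss.backward()
        opt.step()
        trace.append(float(out["loss_rec"].data), float(clu.data), spa_val, float(loss.data))

    final = forward_pass(params, X, A, sample=False)
    emb = EmbeddingSet(H_f=final["H_f"].data, H_g=final["H_g"].data, X_rec=final["X_rec"].data)
    Q = soft_assignment(emb.H, centroids.data)
    state = ClusterState(centroids=centroids.data.copy(), Q=Q, T=target_distribution(Q))
    return emb, state, trace
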