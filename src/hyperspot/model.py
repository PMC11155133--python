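"""The joint embedding model.

Two branches share one reconstruction objective:

* an expression autoencoder — two affine layers with Elu producing a
  low-dimensional expression embedding ``H_f`` (hidden 100, output 20);
* a variational spatial encoder — two independent two-layer hypergraph
  convolutions (no biases),

      HGCN(A, H_f) = A . ReLU(A H_f W_1) W_2          (hidden 32, output 8)

  serving as mean and log-std heads of a diagonal Gaussian over the spatial
  embedding ``H_g``; training samples ``H_g = mu + sigma * eps`` by
  reparameterization, inference uses the mean. No KL prior term is applied
  anywhere — the variational machinery contributes stochastic regularization
  only, and the sole autoencoder objective is the mean-squared reconstruction
  error of the expression matrix from the joint embedding ``H = [H_f, H_g]``
  through a single affine decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .autodiff import Tensor, cat, spmm
from .exceptions import ConfigError, NumericalError

__all__ = [
    "ModelParams",
    "EmbeddingSet",
    "init_params",
    "save_params",
    "load_params",
    "encode_expression",
    "hgcn_forward",
    "vgae_spatial_embedding",
    "decode_reconstruct",
    "reconstruction_loss",
    "forward_pass",
]

LOGSTD_CLAMP = 10.0  # |log sigma| bound before exponentiation, for stability


@dataclass
class ModelParams:
    """All trainable weights. Encoder/decoder are affine; HGCN heads have no biases."""

    W_a: Tensor
    b_a: Tensor
    W_b: Tensor
    b_b: Tensor
    W1_mu: Tensor
    W2_mu: Tensor
    W1_sig: Tensor
    W2_sig: Tensor
    W_dec: Tensor
    b_dec: Tensor

    def trainable(self) -> list[Tensor]:
        return [
            self.W_a, self.b_a, self.W_b, self.b_b,
            self.W1_mu, self.W2_mu, self.W1_sig, self.W2_sig,
            self.W_dec, self.b_dec,
        ]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k).data for k in self.__dataclass_fields__}


@dataclass
class EmbeddingSet:
    """Forward-pass outputs: expression, spatial and joint embeddings + reconstruction."""

    H_f: np.ndarray
    H_g: np.ndarray
    H: np.ndarray = field(init=False)
    X_rec: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.H = np.concatenate([self.H_f, self.H_g], axis=1)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


def init_params(
    n_features: int,
    hidden_f: int = 100,
    d_f: int = 20,
    hidden_g: int = 32,
    d_g: int = 8,
    seed: int = 0,
) -> ModelParams:
    """Glorot-uniform weights, zero biases, all seeded."""
    rng = np.random.default_rng(seed)
    return ModelParams(
        W_a=_glorot(rng, n_features, hidden_f),
        b_a=Tensor(np.zeros(hidden_f), requires_grad=True),
        W_b=_glorot(rng, hidden_f, d_f),
        b_b=Tensor(np.zeros(d_f), requires_grad=True),
        W1_mu=_glorot(rng, d_f, hidden_g),
        W2_mu=_glorot(rng, hidden_g, d_g),
        W1_sig=_glorot(rng, d_f, hidden_g),
        W2_sig=_glorot(rng, hidden_g, d_g),
        W_dec=_glorot(rng, d_f + d_g, n_features),
        b_dec=Tensor(np.zeros(n_features), requires_grad=True),
    )


def save_params(params: ModelParams, path) -> None:
    """Checkpoint: one compressed array archive + a JSON sidecar of shapes."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **params.state_arrays())
    dims = {k: list(v.shape) for k, v in params.state_arrays().items()}
    path.with_suffix(".json").write_text(json.dumps(dims))


def load_params(path) -> ModelParams:
    from pathlib import Path

    arrays = np.load(Path(path).with_suffix(".npz"))
    return ModelParams(**{k: Tensor(arrays[k], requires_grad=True) for k in arrays.files})


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def encode_expression(X, params: ModelParams) -> Tensor:
    """H_f = Elu(Elu(X W_a + b_a) W_b + b_b)."""
    X = _as_tensor(X)
    if X.shape[1] != params.W_a.shape[0]:
        raise ConfigError(
            f"feature dim {X.shape[1]} does not match encoder input {params.W_a.shape[0]}"
        )
    return ((X @ params.W_a + params.b_a).elu() @ params.W_b + params.b_b).elu()


def hgcn_forward(A: sparse.spmatrix | np.ndarray, H_f, W_1: Tensor, W_2: Tensor) -> Tensor:
    """A . ReLU(A H_f W_1) W_2 — the two-layer hypergraph convolution."""
    H_f = _as_tensor(H_f)
    if A.shape[0] != H_f.shape[0]:
        raise ConfigError(f"adjacency is {A.shape} but embedding has {H_f.shape[0]} rows")
    if sparse.issparse(A):
        return spmm(A, (spmm(A, H_f) @ W_1).relu() @ W_2)
    A = _as_tensor(A)
    return A @ ((A @ H_f @ W_1).relu() @ W_2)


def vgae_spatial_embedding(
    A,
    H_f,
    params: ModelParams,
    seed: int | None = None,
    sample: bool = False,
    eps: np.ndarray | None = None,
) -> tuple[Tensor, Tensor, Tensor]:
    """Return (H_g, mu, log_sigma).

    ``mu`` and ``log sigma`` come from independent HGCN heads. With
    ``sample=True`` the embedding is the reparameterized draw
    ``mu + sigma * eps`` (``eps`` standard normal from ``seed`` unless given
    explicitly); otherwise the mean is returned.
    """
    mu = hgcn_forward(A, H_f, params.W1_mu, params.W2_mu)
    log_sigma = hgcn_forward(A, H_f, params.W1_sig, params.W2_sig).clamp(
        -LOGSTD_CLAMP, LOGSTD_CLAMP
    )
    if not np.all(np.isfinite(log_sigma.data)):
        raise NumericalError("non-finite log-sigma in spatial encoder")
    if not sample:
        return mu, mu, log_sigma
    if eps is None:
        eps = np.random.default_rng(seed).standard_normal(mu.shape)
    H_g = mu + log_sigma.exp() * Tensor(eps)
    return H_g, mu, log_sigma


def decode_reconstruct(H, params: ModelParams) -> Tensor:
    """X' = H W_dec + b_dec."""
    H = _as_tensor(H)
    if H.shape[1] != params.W_dec.shape[0]:
        raise ConfigError(
            f"joint dim {H.shape[1]} does not match decoder input {params.W_dec.shape[0]}"
        )
    return H @ params.W_dec + params.b_dec


def reconstruction_loss(X, X_rec) -> Tensor:
    """Mean squared error over all N*F entries."""
    X = _as_tensor(X)
    X_rec = _as_tensor(X_rec)
    diff = X - X_rec
    return (diff * diff).mean(axis=None)


def forward_pass(
    params: ModelParams,
    X: np.ndarray,
    A: sparse.spmatrix,
    sample: bool = False,
    eps: np.ndarray | None = None,
    seed: int | None = None,
) -> dict[str, Tensor]:
    """Full differentiable forward: returns H_f, H_g, mu, log_sigma, H, X_rec, loss_rec."""
    Xt = Tensor(np.asarray(X, dtype=np.float64))
    H_f = encode_expression(Xt, params)
    H_g, mu, log_sigma = vgae_spatial_embedding(A, H_f, params, seed=seed, sample=sample, eps=eps)
    H = cat([H_f, H_g], axis=1)
    X_rec = decode_reconstruct(H, params)
    return {
        "H_f": H_f,
        "H_g": H_g,
        "mu": mu,
        "log_sigma": log_sigma,
        "H": H,
        "X_rec": X_rec,
        "loss_rec": reconstruction_loss(Xt, X_rec),
    }
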