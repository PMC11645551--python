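"""Minimal numpy neural-network core for the superpixel GCN.

The network is two graph-convolution layers (shared normalized adjacency,
ReLU) followed by a per-node linear head whose output passes through
``ELU(x) + 1``, guaranteeing strictly positive predicted expression. It is
small enough (D^2 = 49 nodes, 512 hidden units) that dense numpy matmuls with
hand-written backpropagation and an Adam optimizer are both fast and exactly
reproducible; gradients are verified against finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GCNParams", "init_params", "forward", "loss_and_grads", "Adam"]

HIDDEN_DIM = 512


@dataclass
class GCNParams:
    """Weights of the two GCN layers and the linear output head."""

    W0: np.ndarray  # (C, hidden)
    W1: np.ndarray  # (hidden, hidden)
    W2: np.ndarray  # (hidden, K)
    b: np.ndarray  # (K,)

    @property
    def in_dim(self) -> int:
        return self.W0.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W0.shape[1]

    @property
    def out_dim(self) -> int:
        return self.W2.shape[1]

    def arrays(self) -> dict[str, np.ndarray]:
        return {"W0": self.W0, "W1": self.W1, "W2": self.W2, "b": self.b}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def init_params(
    in_dim: int,
    out_dim: int,
    hidden_dim: int = HIDDEN_DIM,
    seed: int = 0,
    dtype=np.float32,
) -> GCNParams:
    """Seeded Glorot-uniform initialization; zero output bias."""
    rng = np.random.default_rng(seed)
    return GCNParams(
        W0=_glorot(rng, in_dim, hidden_dim, dtype),
        W1=_glorot(rng, hidden_dim, hidden_dim, dtype),
        W2=_glorot(rng, hidden_dim, out_dim, dtype),
        b=np.zeros(out_dim, dtype=dtype),
    )


def _elu_plus_one(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p + 1.0, np.exp(np.minimum(p, 0.0)))


def forward(
    params: GCNParams,
    A: np.ndarray,
    X: np.ndarray,
    return_cache: bool = False,
):
    """Batched forward pass.

    Parameters
    ----------
    A : (N, N) normalized adjacency shared by all graphs in the batch.
    X : (B, N, C) or (N, C) node features.

    Returns
    -------
    Z : (B, N, K) (or (N, K)) strictly positive predicted expression, plus a
        cache of intermediates when ``return_cache``.
    """
    single = X.ndim == 2
    if single:
        X = X[None]
    A = np.asarray(A, dtype=X.dtype)
    S0 = np.einsum("nm,bmc->bnc", A, X)
    P0 = S0 @ params.W0
    H1 = np.maximum(P0, 0.0)
    S1 = np.einsum("nm,bmc->bnc", A, H1)
    P1 = S1 @ params.W1
    H2 = np.maximum(P1, 0.0)
    P2 = H2 @ params.W2 + params.b
    Z = _elu_plus_one(P2)
    if single:
        Z = Z[0]
    if not return_cache:
        return Z
    cache = {"S0": S0, "P0": P0, "H1": H1, "S1": S1, "P1": P1, "H2": H2, "P2": P2}
    return Z, cache


def loss_and_grads(
    params: GCNParams,
    A: np.ndarray,
    X: np.ndarray,
    filters: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Weak-supervision squared loss and its exact gradients.

    For each spot j the in-disc prediction sum ``M_j = sum_n filter_jn Z_jn``
    is compared with the observed spot vector ``g_j``; the loss is
    ``sum_j ||g_j - M_j||^2`` over the batch.

    Parameters
    ----------
    X : (B, N, C) patch features; filters : (B, N) boolean; labels : (B, K).
    """
    Z, c = forward(params, A, X, return_cache=True)
    f = filters.astype(X.dtype)
    M = np.einsum("bn,bnk->bk", f, Z)
    R = M - labels.astype(X.dtype)
    loss = float(np.sum(R * R))

    dZ = 2.0 * f[:, :, None] * R[:, None, :]
    dP2 = dZ * np.where(c["P2"] > 0, 1.0, np.exp(np.minimum(c["P2"], 0.0)))
    gW2 = np.einsum("bnh,bnk->hk", c["H2"], dP2)
    gb = dP2.sum(axis=(0, 1))
    dH2 = dP2 @ params.W2.T
    dP1 = dH2 * (c["P1"] > 0)
    gW1 = np.einsum("bnh,bng->hg", c["S1"], dP1)
    dS1 = dP1 @ params.W1.T
    A = np.asarray(A, dtype=X.dtype)
    dH1 = np.einsum("mn,bmc->bnc", A, dS1)  # A^T, A symmetric in practice
    dP0 = dH1 * (c["P0"] > 0)
    gW0 = np.einsum("bnc,bnh->ch", c["S0"], dP0)
    grads = {
        "W0": gW0.astype(params.W0.dtype),
        "W1": gW1.astype(params.W1.dtype),
        "W2": gW2.astype(params.W2.dtype),
        "b": gb.astype(params.b.dtype),
    }
    return loss, grads


@dataclass
class Adam:
    """Standard Adam optimizer with bias correction."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: GCNParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        arrays = params.arrays()
        for key, g in grads.items():
            p = arrays[key]
            if key not in self.m:
                self.m[key] = np.zeros_like(p)
                self.v[key] = np.zeros_like(p)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * (g * g)
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            p -= (self.learning_rate * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.dtype
            )
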