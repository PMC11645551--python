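"""Grid-graph construction for per-spot patches.

Every spot patch is a D x D block of superpixels; D is the number of
superpixels spanned by the spot diameter. Each superpixel is a node and its
four nearest neighbours by physical distance — up, down, left, right on the
square grid — form the edges. Because every patch shares this topology, one
normalized adjacency is built once and reused for all spots and all inference
tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse

__all__ = ["GridGraph", "compute_patch_span", "build_adjacency"]


def compute_patch_span(diameter_um: float, superpixel_um: float) -> int:
    """Number of superpixels spanned by a spot diameter, D = round(d/s).

    Round-half-up (55/8 -> 7, 100/8 -> 13), floored at 1.
    """
    if diameter_um <= 0 or superpixel_um <= 0:
        raise ValueError("diameter_um and superpixel_um must be positive")
    return max(1, int(np.floor(diameter_um / superpixel_um + 0.5)))


@dataclass(frozen=True)
class GridGraph:
    """Shared D x D grid graph with its normalized adjacency.

    ``adjacency`` is the dense normalized operator actually multiplied in the
    network; ``adjacency_raw`` the unnormalized 0/1 grid adjacency (no self
    loops). Node ordering is the row-major flatten of the D x D block.
    """

    D: int
    adjacency: np.ndarray
    adjacency_raw: scipy.sparse.csr_matrix
    normalization: str

    @property
    def n_nodes(self) -> int:
        return self.D * self.D


def build_adjacency(D: int, normalization: str = "sym") -> GridGraph:
    """Build the shared spot-patch graph.

    Parameters
    ----------
    D : int
        Patch side in superpixels.
    normalization : {"sym", "row", "none"}
        "sym": add self-loops and apply symmetric degree normalization
        ``D^{-1/2} (A + I) D^{-1/2}`` (default; standard GCN operator).
        "row": add self-loops and normalize rows to sum to 1.
        "none": the raw 4-neighbour adjacency, as written in the plain
        graph-convolution formulation, kept for fidelity experiments.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if normalization not in ("sym", "row", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    n = D * D
    rows, cols = [], []
    for m in range(D):
        for k in range(D):
            u = m * D + k
            if m + 1 < D:
                v = (m + 1) * D + k
                rows += [u, v]
                cols += [v, u]
            if k + 1 < D:
                v = m * D + (k + 1)
                rows += [u, v]
                cols += [v, u]
    raw = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    if normalization == "none":
        ahat = raw.toarray()
    else:
        a_tilde = raw.toarray() + np.eye(n)
        deg = a_tilde.sum(axis=1)
        if normalization == "sym":
            d_inv_sqrt = 1.0 / np.sqrt(deg)
            ahat = d_inv_sqrt[:, None] * a_tilde * d_inv_sqrt[None, :]
        else:  # row
            ahat = a_tilde / deg[:, None]
    return GridGraph(D=D, adjacency=ahat, adjacency_raw=raw, normalization=normalization)
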