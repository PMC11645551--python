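"""Weakly supervised super-resolution of spot-based spatial transcriptomics.

The estimator learns a map from per-superpixel multimodal features (histology
backbone + position + RGB) to per-superpixel gene expression, supervised only
at spot level: for every capture spot, the predicted expression summed over
the superpixels inside the spot's circular footprint must match the observed
spot vector. Each spot contributes one D x D patch of the feature map; all
patches share a single 4-neighbour grid graph, so the network — two graph
convolutions into 512-dimensional node features plus a linear head with an
``ELU + 1`` output — is trained by mini-batch Adam on the squared spot-sum
residuals, then slid tile-by-tile over the whole feature map for inference.

The public surface follows the model/results idiom: build a
:class:`SuperResolutionGCN` from data, call :meth:`~SuperResolutionGCN.fit`,
and use the returned :class:`SuperResolutionGCNResults` to predict, export
intermediate GCN features, or summarize the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .features import MultimodalFeatureMap
from .graph import GridGraph, build_adjacency, compute_patch_span
from .grid import HighResExpression, SpotExpression, SpotLayout, SuperpixelGrid

__all__ = [
    "SpotPatch",
    "TrainConfig",
    "build_spot_patches",
    "gcn_forward",
    "weak_supervision_loss",
    "train",
    "infer_superres",
    "export_gcn_features",
    "SuperResolutionGCN",
    "SuperResolutionGCNResults",
]


@dataclass(frozen=True)
class SpotPatch:
    """One spot's training example.

    ``features`` is the D x D x C block of the multimodal map centered on the
    superpixel containing the spot center (zero-padded at map borders);
    ``filter`` flags the superpixels whose centers fall inside the spot disc
    (always false over border padding); ``label`` is the observed spot vector.
    """

    features: np.ndarray
    filter: np.ndarray
    label: np.ndarray
    spot_id: int

    def __post_init__(self) -> None:
        if self.features.ndim != 3 or self.filter.shape != self.features.shape[:2]:
            raise ValueError("features must be (D, D, C) with a matching filter")
        if not self.filter.any():
            raise ValueError("circular filter must select at least one superpixel")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (values the underlying method leaves open).

    learning_rate / batch_size / epochs drive mini-batch Adam on the training
    loss; ``patience`` stops early when the epoch loss has not improved for
    that many epochs. ``device`` is accepted for interface compatibility; this
    implementation computes on the CPU.
    """

    learning_rate: float = 2e-3
    batch_size: int = 32
    epochs: int = 500
    seed: int = 0
    patience: int = 50
    device: str = "cpu"

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs, self.patience) <= 0:
            raise ValueError("all TrainConfig numeric fields must be positive")


def build_spot_patches(
    fmap: MultimodalFeatureMap,
    layout: SpotLayout,
    spot_expr: SpotExpression,
    D: int | None = None,
) -> list[SpotPatch]:
    """Cut one D x D feature patch (plus disc filter and label) per spot.

    The patch's top-left superpixel is the spot's center superpixel minus
    ``floor(D/2)``; blocks reaching past the map border are zero-padded with
    the filter false there. Spots whose center superpixel lies off the map are
    skipped with a warning.
    """
    grid = fmap.grid
    if D is None:
        D = compute_patch_span(layout.diameter_um, grid.superpixel_um)
    half = D // 2
    C = fmap.n_channels
    feats = np.moveaxis(fmap.channels, 0, -1)  # (R, C, C_feat)
    xg, yg = grid.superpixel_centers_um()
    patches: list[SpotPatch] = []
    r = layout.radius_um
    for j, (cx, cy) in enumerate(layout.centers_um):
        m, n = grid.superpixel_of(cx, cy)
        if not (0 <= m < grid.n_rows and 0 <= n < grid.n_cols):
            warnings.warn(f"spot {j} center lies off the feature map; skipped",
                          stacklevel=2)
            continue
        m0, n0 = m - half, n - half
        block = np.zeros((D, D, C), dtype=feats.dtype)
        filt = np.zeros((D, D), dtype=bool)
        r0, r1 = max(m0, 0), min(m0 + D, grid.n_rows)
        c0, c1 = max(n0, 0), min(n0 + D, grid.n_cols)
        block[r0 - m0 : r1 - m0, c0 - n0 : c1 - n0] = feats[r0:r1, c0:c1]
        dx = xg[r0:r1, c0:c1] - cx
        dy = yg[r0:r1, c0:c1] - cy
        filt[r0 - m0 : r1 - m0, c0 - n0 : c1 - n0] = dx * dx + dy * dy <= r * r
        if not filt.any():
            warnings.warn(f"spot {j} covers no superpixel center; skipped",
                          stacklevel=2)
            continue
        patches.append(
            SpotPatch(features=block, filter=filt, label=spot_expr.counts[j],
                      spot_id=j)
        )
    return patches


def gcn_forward(
    params: nn.GCNParams, patch_features: np.ndarray, graph: GridGraph
) -> np.ndarray:
    """Predict a (D^2, K) non-negative expression matrix for one patch.

    Node order is the row-major flatten of the D x D block.
    """
    D = graph.D
    if patch_features.shape[:2] != (D, D):
        raise ValueError(
            f"patch is {patch_features.shape[:2]}, graph expects ({D}, {D})"
        )
    if patch_features.shape[2] != params.in_dim:
        raise ValueError(
            f"patch has {patch_features.shape[2]} channels, model expects "
            f"{params.in_dim}"
        )
    X = patch_features.reshape(D * D, -1)
    return nn.forward(params, graph.adjacency, X)


def weak_supervision_loss(
    pred: np.ndarray, filt: np.ndarray, label: np.ndarray
) -> float:
    """Squared distance between the in-disc prediction sum and the spot label.

    ``pred`` is (D^2, K), ``filt`` the D x D (or flat D^2) disc mask, ``label``
    the length-K observed vector. Summed over genes; batching over spots is a
    plain sum of per-spot terms.
    """
    f = np.asarray(filt, dtype=bool).ravel()
    if not f.any():
        warnings.warn("empty circular filter; spot excluded from the loss",
                      stacklevel=2)
        return 0.0
    m = pred[f].sum(axis=0)
    d = m - np.asarray(label, dtype=pred.dtype)
    return float(np.dot(d, d))


def _stack_patches(patches: list[SpotPatch], dtype=np.float32):
    X = np.stack([p.features.reshape(-1, p.features.shape[-1]) for p in patches])
    F = np.stack([p.filter.ravel() for p in patches])
    G = np.stack([p.label for p in patches])
    return X.astype(dtype), F, G.astype(dtype)


def train(
    patches: list[SpotPatch],
    graph: GridGraph,
    config: TrainConfig | None = None,
    hidden_dim: int = nn.HIDDEN_DIM,
) -> tuple[nn.GCNParams, list[float]]:
    """Fit the network by mini-batch Adam on the weak-supervision loss.

    Deterministic given the seed: weight init and the per-epoch shuffling both
    derive from ``config.seed``. Returns the fitted parameters and the
    per-epoch total training loss. Raises on a non-finite loss.
    """
    if config is None:
        config = TrainConfig()
    if len(patches) < 2:
        raise ValueError("training requires at least 2 spots")
    X, F, G = _stack_patches(patches)
    n_spots = X.shape[0]
    params = nn.init_params(
        X.shape[2], G.shape[1], hidden_dim=hidden_dim, seed=config.seed
    )
    opt = nn.Adam(learning_rate=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    A = graph.adjacency.astype(X.dtype)
    history: list[float] = []
    best, since_best = np.inf, 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n_spots)
        epoch_loss = 0.0
        for start in range(0, n_spots, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = nn.loss_and_grads(params, A, X[idx], F[idx], G[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {_epoch}; "
                    "reduce the learning rate or rescale the inputs"
                )
            opt.step(params, grads)
            epoch_loss += loss
        history.append(epoch_loss)
        if epoch_loss < best - 1e-12:
            best, since_best = epoch_loss, 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return params, history


def _tile_batches(channels: np.ndarray, D: int):
    """Zero-pad the (C, R, Co) map to multiples of D and cut D x D tiles."""
    C, R, Co = channels.shape
    pr, pc = (-R) % D, (-Co) % D
    padded = np.pad(channels, ((0, 0), (0, pr), (0, pc)))
    Rt, Ct = (R + pr) // D, (Co + pc) // D
    tiles = (
        padded.reshape(C, Rt, D, Ct, D)
        .transpose(1, 3, 2, 4, 0)
        .reshape(Rt * Ct, D * D, C)
    )
    return tiles, (Rt, Ct), (pr, pc)


def _assemble(tiles_out: np.ndarray, D: int, shape_tiles, pad, out_hw):
    Rt, Ct = shape_tiles
    K = tiles_out.shape[-1]
    full = (
        tiles_out.reshape(Rt, Ct, D, D, K)
        .transpose(0, 2, 1, 3, 4)
        .reshape(Rt * D, Ct * D, K)
    )
    return full[: out_hw[0], : out_hw[1]]


def infer_superres(
    fmap: MultimodalFeatureMap,
    params: nn.GCNParams,
    graph: GridGraph,
    mask: np.ndarray | None = None,
    batch_tiles: int = 64,
    gene_names: tuple[str, ...] | None = None,
) -> HighResExpression:
    """Tile the whole feature map and predict every superpixel's expression.

    The map is zero-padded to multiples of D, divided into non-overlapping
    D x D tiles, each predicted with the shared graph and model, reassembled in
    place, cropped back, and zeroed outside the tissue mask.
    """
    if fmap.n_channels != params.in_dim:
        raise ValueError(
            f"feature map has {fmap.n_channels} channels, model expects "
            f"{params.in_dim}"
        )
    if mask is None:
        mask = fmap.mask
    D = graph.D
    tiles, shape_tiles, pad = _tile_batches(fmap.channels, D)
    A = graph.adjacency
    outs = []
    for start in range(0, len(tiles), batch_tiles):
        X = tiles[start : start + batch_tiles].astype(np.float32)
        outs.append(nn.forward(params, A.astype(np.float32), X))
    Z = np.concatenate(outs, axis=0)
    values = _assemble(Z, D, shape_tiles, pad, fmap.shape).astype(float)
    values[~mask] = 0.0
    if gene_names is None:
        genes = tuple(f"gene_{k}" for k in range(params.out_dim))
    else:
        if len(gene_names) != params.out_dim:
            raise ValueError("gene_names length must match the model output")
        genes = tuple(gene_names)
    return HighResExpression(
        values=values, mask=np.asarray(mask, dtype=bool), grid=fmap.grid,
        gene_names=genes,
    )


def export_gcn_features(
    fmap: MultimodalFeatureMap,
    params: nn.GCNParams,
    graph: GridGraph,
    mask: np.ndarray | None = None,
    batch_tiles: int = 64,
) -> np.ndarray:
    """Per-superpixel second-layer GCN activations, (512, R, C), masked to 0.

    These are the representations used downstream for tissue segmentation.
    """
    if mask is None:
        mask = fmap.mask
    D = graph.D
    tiles, shape_tiles, pad = _tile_batches(fmap.channels, D)
    A = graph.adjacency.astype(np.float32)
    outs = []
    for start in range(0, len(tiles), batch_tiles):
        X = tiles[start : start + batch_tiles].astype(np.float32)
        _, cache = nn.forward(params, A, X, return_cache=True)
        outs.append(cache["H2"])
    H2 = np.concatenate(outs, axis=0)
    field_hw = _assemble(H2, D, shape_tiles, pad, fmap.shape).astype(float)
    field_hw[~np.asarray(mask, dtype=bool)] = 0.0
    return np.moveaxis(field_hw, -1, 0)


class SuperResolutionGCN:
    """Super-resolution model tying a feature map to spot-level supervision.

    Parameters
    ----------
    feature_map : MultimodalFeatureMap
        Per-superpixel multimodal descriptors (histology + position + RGB).
    spot_expr : SpotExpression
        Observed spot-level expression; its layout provides spot geometry.
    config : TrainConfig, optional
        Optimization settings; defaults are used when omitted.
    adjacency_normalization : {"sym", "row", "none"}
        Normalization of the shared grid-graph operator.
    hidden_dim : int
        Width of the two graph-convolution layers (512 by default).
    normalize_depth : bool
        When set, spot labels are rescaled to the median library size before
        training (off by default: pseudo-Visium labels are exact in-disc sums
        and real Visium depth effects are usually mild at this scale).

    Examples
    --------
    >>> model = SuperResolutionGCN(fmap, spots)          # doctest: +SKIP
    >>> res = model.fit()                                # doctest: +SKIP
    >>> highres = res.predict()                          # doctest: +SKIP
    """

    def __init__(
        self,
        feature_map: MultimodalFeatureMap,
        spot_expr: SpotExpression,
        config: TrainConfig | None = None,
        adjacency_normalization: str = "sym",
        hidden_dim: int = nn.HIDDEN_DIM,
        normalize_depth: bool = False,
    ):
        if normalize_depth:
            lib = spot_expr.counts.sum(axis=1)
            target = float(np.median(lib[lib > 0])) if np.any(lib > 0) else 1.0
            scale = np.divide(target, lib, out=np.zeros_like(lib), where=lib > 0)
            spot_expr = SpotExpression(
                counts=spot_expr.counts * scale[:, None],
                gene_names=spot_expr.gene_names,
                layout=spot_expr.layout,
            )
        self.feature_map = feature_map
        self.spot_expr = spot_expr
        self.layout = spot_expr.layout
        self.config = config or TrainConfig()
        self.hidden_dim = hidden_dim
        self.normalize_depth = normalize_depth
        self.D = compute_patch_span(
            self.layout.diameter_um, feature_map.grid.superpixel_um
        )
        self.graph = build_adjacency(self.D, adjacency_normalization)
        self.patches = build_spot_patches(
            feature_map, self.layout, spot_expr, self.D
        )

    @property
    def n_spots(self) -> int:
        return len(self.patches)

    @property
    def n_genes(self) -> int:
        return self.spot_expr.n_genes

    def fit(self, **overrides) -> "SuperResolutionGCNResults":
        """Train the network; keyword overrides update the TrainConfig."""
        config = replace(self.config, **overrides) if overrides else self.config
        params, history = train(
            self.patches, self.graph, config, hidden_dim=self.hidden_dim
        )
        return SuperResolutionGCNResults(
            model=self, params=params, loss_history=history, config=config
        )


@dataclass
class SuperResolutionGCNResults:
    """Fitted super-resolution model: weights, training diagnostics, inference."""

    model: SuperResolutionGCN
    params: nn.GCNParams
    loss_history: list[float]
    config: TrainConfig

    def predict(
        self,
        feature_map: MultimodalFeatureMap | None = None,
        mask: np.ndarray | None = None,
    ) -> HighResExpression:
        """Superpixel-level expression for the training map (default) or any
        other map with the same channel layout (transfer inference)."""
        fmap = feature_map if feature_map is not None else self.model.feature_map
        return infer_superres(
            fmap, self.params, self.model.graph, mask=mask,
            gene_names=self.model.spot_expr.gene_names,
        )

    def gcn_features(
        self,
        feature_map: MultimodalFeatureMap | None = None,
        mask: np.ndarray | None = None,
    ) -> np.ndarray:
        fmap = feature_map if feature_map is not None else self.model.feature_map
        return export_gcn_features(fmap, self.params, self.model.graph, mask=mask)

    def spot_sum_consistency(self) -> np.ndarray:
        """Per-spot relative error between in-disc prediction sums and labels.

        The training constraint, evaluated after fitting: for each spot,
        ``|label - in-disc sum|_2 / |label|_2`` (spots with zero labels are
        skipped).
        """
        X, F, G = _stack_patches(self.model.patches)
        Z = nn.forward(
            self.params, self.model.graph.adjacency.astype(np.float32), X
        )
        M = np.einsum("bn,bnk->bk", F.astype(np.float32), Z)
        norms = np.linalg.norm(G, axis=1)
        keep = norms > 0
        return np.linalg.norm(M[keep] - G[keep], axis=1) / norms[keep]

    def summary(self) -> str:
        m = self.model
        err = self.spot_sum_consistency()
        lines = [
            "Super-resolution GCN results",
            "=" * 46,
            f"spots (training patches)      {m.n_spots}",
            f"genes                         {m.n_genes}",
            f"input channels                {m.feature_map.n_channels}",
            f"patch span D                  {m.D} ({m.D * m.D} nodes)",
            f"hidden dimension              {m.hidden_dim}",
            f"adjacency normalization       {m.graph.normalization}",
            f"epochs run                    {len(self.loss_history)}",
            f"initial epoch loss            {self.loss_history[0]:.6g}",
            f"final epoch loss              {self.loss_history[-1]:.6g}",
            f"median spot-sum rel. error    {np.median(err):.4f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize weights + config + seed as a versioned npz archive."""
        np.savez(
            path,
            format_version=1,
            gene_names=np.array(self.model.spot_expr.gene_names),
            W0=self.params.W0,
            W1=self.params.W1,
            W2=self.params.W2,
            b=self.params.b,
            loss_history=np.asarray(self.loss_history),
            learning_rate=self.config.learning_rate,
            batch_size=self.config.batch_size,
            epochs=self.config.epochs,
            seed=self.config.seed,
            patience=self.config.patience,
        )

    @staticmethod
    def load_params(
        path,
    ) -> tuple[nn.GCNParams, TrainConfig, list[float], tuple[str, ...]]:
        with np.load(path) as f:
            genes = tuple(str(g) for g in f["gene_names"])
            params = nn.GCNParams(
                W0=f["W0"], W1=f["W1"], W2=f["W2"], b=f["b"]
            )
            config = TrainConfig(
                learning_rate=float(f["learning_rate"]),
                batch_size=int(f["batch_size"]),
                epochs=int(f["epochs"]),
                seed=int(f["seed"]),
                patience=int(f["patience"]),
            )
            history = [float(x) for x in f["loss_history"]]
        return params, config, history, genes
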