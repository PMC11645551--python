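"""Gene-wise evaluation of predicted super-resolution expression.

Each gene's 2-D map is min-max normalized over the tissue mask before scoring,
making RMSE/SSIM comparable across genes of very different depth. Spot-only
datasets are scored by re-aggregating predictions under the observed spot
discs and comparing spot vectors (RMSE, PCC, MAE; SSIM needs 2-D structure and
is skipped there). Also provided: marker-panel scoring (normalized-average of
marker maps, the usual tertiary-lymphoid-structure readout) and k-means tissue
segmentation on learned GCN features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from sklearn.cluster import KMeans

from .aggregate import reaggregate_to_spots
from .grid import HighResExpression, SpotExpression

__all__ = [
    "GeneMetrics",
    "normalize_gene_map",
    "gene_rmse",
    "gene_mae",
    "gene_pcc",
    "gene_ssim",
    "evaluate_highres",
    "evaluate_at_spots",
    "tls_score",
    "segment_tissue",
    "compare_segmentations",
]

SSIM_WIN = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03


@dataclass(frozen=True)
class GeneMetrics:
    """Per-gene metric table plus median/mean summaries.

    ``per_gene`` has one row per gene with columns among
    {rmse, ssim, pcc, mae, flagged}; flagged genes (zero variance after
    normalization) are excluded from the summaries.
    """

    per_gene: pd.DataFrame
    summary: dict[str, float]

    def to_csv(self, path) -> None:
        self.per_gene.to_csv(path, index=True, index_label="gene")


def normalize_gene_map(
    field: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Min-max normalize a 2-D map over masked entries to [0, 1].

    Returns ``(normalized, constant_flag)``; constant maps come back all-zero
    with the flag set. Entries outside the mask are zeroed.
    """
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no entries")
    vals = field[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(field)
    if hi - lo <= 0:
        return out, True
    out[mask] = (vals - lo) / (hi - lo)
    return out, False


def _check_pair(pred, truth, mask):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != truth.shape or mask.shape != pred.shape:
        raise ValueError("pred, truth and mask must share a shape")
    if not mask.any():
        raise ValueError("mask selects no entries")
    return pred, truth, mask


def gene_rmse(pred: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    pred, truth, mask = _check_pair(pred, truth, mask)
    d = pred[mask] - truth[mask]
    return float(np.sqrt(np.mean(d * d)))


def gene_mae(pred: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    pred, truth, mask = _check_pair(pred, truth, mask)
    return float(np.mean(np.abs(pred[mask] - truth[mask])))


def gene_pcc(pred: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation over masked entries; NaN when either side is
    constant (flagged undefined upstream)."""
    pred, truth, mask = _check_pair(pred, truth, mask)
    a, b = pred[mask], truth[mask]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def gene_ssim(pred: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """Mean structural similarity over masked window centers.

    Standard SSIM with an 11x11 Gaussian window (sigma 1.5), K1=0.01,
    K2=0.03 and data range 1.0 — intended for maps already normalized to
    [0, 1]. The local SSIM image is computed on the full maps and averaged
    over the mask.
    """
    pred, truth, mask = _check_pair(pred, truth, mask)
    _, smap = structural_similarity(
        truth,
        pred,
        win_size=SSIM_WIN,
        gaussian_weights=True,
        sigma=SSIM_SIGMA,
        K1=SSIM_K1,
        K2=SSIM_K2,
        data_range=1.0,
        use_sample_covariance=False,
        full=True,
    )
    return float(smap[mask].mean())


def evaluate_highres(
    pred: HighResExpression, truth: HighResExpression,
    genes: list[str] | None = None,
) -> GeneMetrics:
    """Score predicted against true superpixel fields, gene by gene.

    Both maps are min-max normalized over the shared mask; flagged
    (constant) genes get NaN metrics and are excluded from the summary
    median/mean.
    """
    if pred.values.shape[:2] != truth.values.shape[:2]:
        raise ValueError("prediction and truth grids differ")
    if genes is None:
        genes = [g for g in truth.gene_names if g in set(pred.gene_names)]
    if not genes:
        raise ValueError("prediction and truth share no gene names")
    mask = pred.mask & truth.mask
    rows = []
    for g in genes:
        p, pflag = normalize_gene_map(pred.gene_map(g), mask)
        t, tflag = normalize_gene_map(truth.gene_map(g), mask)
        flagged = pflag or tflag
        if flagged:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, True))
            continue
        rows.append(
            (
                g,
                gene_rmse(p, t, mask),
                gene_ssim(p, t, mask),
                gene_pcc(p, t, mask),
                gene_mae(p, t, mask),
                False,
            )
        )
    df = pd.DataFrame(
        rows, columns=["gene", "rmse", "ssim", "pcc", "mae", "flagged"]
    ).set_index("gene")
    ok = df[~df["flagged"]]
    summary = {}
    for metric in ("rmse", "ssim", "pcc", "mae"):
        vals = ok[metric].dropna()
        summary[f"median_{metric}"] = float(vals.median()) if len(vals) else float("nan")
        summary[f"mean_{metric}"] = float(vals.mean()) if len(vals) else float("nan")
    return GeneMetrics(per_gene=df, summary=summary)


def evaluate_at_spots(
    pred: HighResExpression, observed: SpotExpression
) -> GeneMetrics:
    """Score a prediction against spot-level data (spot-only datasets).

    Predictions are summed under each observed spot disc; per gene, the spot
    vectors of prediction and observation are min-max normalized and compared
    with RMSE, PCC and MAE (no SSIM for 1-D spot vectors).
    """
    agg = reaggregate_to_spots(pred, observed.layout)
    common = [g for g in observed.gene_names if g in set(agg.gene_names)]
    rows = []
    ones = np.ones(observed.counts.shape[0], dtype=bool)
    for g in common:
        pv = agg.counts[:, agg.gene_names.index(g)]
        ov = observed.counts[:, observed.gene_names.index(g)]
        p, pflag = normalize_gene_map(pv, ones)
        o, oflag = normalize_gene_map(ov, ones)
        if pflag or oflag:
            rows.append((g, np.nan, np.nan, np.nan, True))
            continue
        rows.append(
            (g, gene_rmse(p, o, ones), gene_pcc(p, o, ones), gene_mae(p, o, ones),
             False)
        )
    df = pd.DataFrame(rows, columns=["gene", "rmse", "pcc", "mae", "flagged"])
    df = df.set_index("gene")
    ok = df[~df["flagged"]]
    summary = {}
    for metric in ("rmse", "pcc", "mae"):
        vals = ok[metric].dropna()
        summary[f"median_{metric}"] = float(vals.median()) if len(vals) else float("nan")
        summary[f"mean_{metric}"] = float(vals.mean()) if len(vals) else float("nan")
    return GeneMetrics(per_gene=df, summary=summary)


def tls_score(
    highres: HighResExpression, marker_genes: list[str]
) -> np.ndarray:
    """Marker-panel score map: mean of min-max-normalized marker maps.

    The usual readout for tertiary lymphoid structures: each marker gene's
    field is normalized to [0, 1] over the mask, then averaged across the
    panel. Markers absent from the data are skipped with a warning.
    """
    present = [g for g in marker_genes if g in highres.gene_names]
    missing = [g for g in marker_genes if g not in highres.gene_names]
    if missing:
        warnings.warn(f"marker genes not in data, skipped: {missing}", stacklevel=2)
    if not present:
        raise ValueError("none of the marker genes are present")
    acc = np.zeros(highres.mask.shape)
    for g in present:
        normed, _ = normalize_gene_map(highres.gene_map(g), highres.mask)
        acc += normed
    return acc / len(present)


def segment_tissue(
    gcn_features: np.ndarray,
    mask: np.ndarray,
    k: int,
    seed: int = 0,
) -> np.ndarray:
    """k-means tissue segmentation on per-superpixel feature vectors.

    Features are (C, R, Co); clustering uses k-means++ with 10 restarts at a
    fixed seed, and labels are relabeled by descending cluster size so the
    output is deterministic. Superpixels outside the mask get label -1.
    """
    feats = np.moveaxis(np.asarray(gcn_features, dtype=float), 0, -1)
    mask = np.asarray(mask, dtype=bool)
    labels = np.full(mask.shape, -1, dtype=int)
    if not mask.any():
        return labels
    X = feats[mask]
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels[mask] = remap[raw]
    return labels


def compare_segmentations(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two label maps, over jointly labeled
    entries (label -1 marks out-of-mask)."""
    from sklearn.metrics import adjusted_rand_score

    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("label maps must share a shape")
    keep = (a >= 0) & (b >= 0)
    return float(adjusted_rand_score(a[keep], b[keep]))
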