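"""Aggregation between resolution levels and highly-variable-gene selection.

These operations implement the pseudo-Visium benchmark construction: cell-level
expression is partitioned onto the superpixel grid by exact overlap area;
spot-level data is simulated by summing cells (centroid-in-disc membership) or
superpixels (center-in-disc membership) under a Visium-like spot layout. The
same superpixel aggregation, driven by observed spot centers, re-aggregates
model output to spot level for evaluation on spot-only datasets.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .grid import (
    CellTable,
    HighResExpression,
    SpotExpression,
    SpotLayout,
    SuperpixelGrid,
)

__all__ = [
    "cells_to_superpixels",
    "pseudo_visium_from_cells",
    "pseudo_visium_from_bins",
    "reaggregate_to_spots",
    "select_hvg",
    "uniform_disaggregation",
]


def cells_to_superpixels(
    cells: CellTable,
    grid: SuperpixelGrid,
    gene_names: tuple[str, ...] | None = None,
) -> HighResExpression:
    """Partition cell-level expression onto the superpixel grid by overlap area.

    Each cell k with footprint area A_k contributes the fraction
    ``A_kmn / A_k`` of its expression vector to superpixel (m, n), where A_kmn
    is the exact overlap area between the cell footprint and the superpixel
    square — closed form for axis-aligned boxes (the default equal-area square
    when no footprint is given), polygon intersection when explicit polygon
    footprints are provided. Total expression is conserved for cells whose
    footprint lies fully inside the grid. Cells entirely outside the grid are
    excluded with a warning.
    """
    if gene_names is None:
        gene_names = cells.gene_names
    s = grid.superpixel_um
    ox, oy = grid.origin_um
    xmin_g, ymin_g, xmax_g, ymax_g = grid.bbox_um()
    values = np.zeros((grid.n_rows, grid.n_cols, len(gene_names)))
    boxes = cells.footprint_boxes()
    polygons = cells.footprints if cells.has_polygon_footprints else None
    if polygons is not None:
        from shapely.geometry import box as shapely_box
    n_outside = 0
    for k in range(cells.n_cells):
        bx0, by0, bx1, by1 = boxes[k]
        if bx1 - bx0 <= 0 or by1 - by0 <= 0:
            raise ValueError(f"cell {k} has a zero-area footprint")
        if bx1 <= xmin_g or bx0 >= xmax_g or by1 <= ymin_g or by0 >= ymax_g:
            n_outside += 1
            continue
        area = (
            polygons[k].area if polygons is not None
            else (bx1 - bx0) * (by1 - by0)
        )
        # candidate superpixel index range covered by the footprint bounds
        n0 = max(0, int(np.floor((bx0 - ox) / s)))
        n1 = min(grid.n_cols - 1, int(np.floor((bx1 - ox) / s - 1e-12)))
        m0 = max(0, int(np.floor((by0 - oy) / s)))
        m1 = min(grid.n_rows - 1, int(np.floor((by1 - oy) / s - 1e-12)))
        for m in range(m0, m1 + 1):
            oy_m = oy + m * s
            for n in range(n0, n1 + 1):
                ox_n = ox + n * s
                if polygons is not None:
                    overlap = polygons[k].intersection(
                        shapely_box(ox_n, oy_m, ox_n + s, oy_m + s)
                    ).area
                else:
                    dy = min(by1, oy_m + s) - max(by0, oy_m)
                    dx = min(bx1, ox_n + s) - max(bx0, ox_n)
                    overlap = max(dx, 0.0) * max(dy, 0.0)
                if overlap > 0:
                    values[m, n] += (overlap / area) * cells.cell_expression[k]
    if n_outside:
        warnings.warn(
            f"{n_outside} cell(s) lie entirely outside the grid and were excluded",
            stacklevel=2,
        )
    mask = values.sum(axis=2) > 0
    return HighResExpression(values=values, mask=mask, grid=grid, gene_names=gene_names)


def pseudo_visium_from_cells(
    cells: CellTable,
    layout: SpotLayout,
    gene_names: tuple[str, ...] | None = None,
) -> SpotExpression:
    """Simulate spot-level data by summing the cells covered by each spot.

    A cell belongs to a spot when its centroid lies within the spot radius of
    the spot center (all-or-nothing membership). With pitch >= diameter the
    discs are disjoint, so each cell contributes to at most one spot.
    """
    if gene_names is None:
        gene_names = cells.gene_names
    counts = np.zeros((layout.n_spots, len(gene_names)))
    if cells.n_cells:
        d = cdist(layout.centers_um, cells.centroids_um)
        member = d <= layout.radius_um
        counts = member.astype(float) @ cells.cell_expression
    return SpotExpression(counts=counts, gene_names=gene_names, layout=layout)


def _bins_to_spots(highres: HighResExpression, layout: SpotLayout) -> np.ndarray:
    xg, yg = highres.grid.superpixel_centers_um()
    centers = np.stack([xg.ravel(), yg.ravel()], axis=1)
    flat = highres.values.reshape(-1, highres.n_genes)
    d = cdist(layout.centers_um, centers)
    member = d <= layout.radius_um
    empty = ~member.any(axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} spot(s) cover no superpixel center; their rows are zero",
            stacklevel=3,
        )
    return member.astype(float) @ flat


def pseudo_visium_from_bins(
    highres: HighResExpression, layout: SpotLayout
) -> SpotExpression:
    """Simulate spot-level data from a gapless binned grid (Visium-HD-like).

    Spot j receives the sum of all superpixels whose centers lie within the
    spot radius of the spot center.
    """
    counts = _bins_to_spots(highres, layout)
    return SpotExpression(counts=counts, gene_names=highres.gene_names, layout=layout)


def reaggregate_to_spots(
    pred: HighResExpression, layout: SpotLayout
) -> SpotExpression:
    """Sum predicted superpixels under observed spot discs.

    Identical arithmetic to :func:`pseudo_visium_from_bins`, but intended for
    the evaluation path on spot-only datasets, where the spot centers come from
    the measured data rather than a simulated lattice.
    """
    counts = _bins_to_spots(pred, layout)
    return SpotExpression(counts=counts, gene_names=pred.gene_names, layout=layout)


def uniform_disaggregation(
    spot_expr: SpotExpression, grid: SuperpixelGrid
) -> HighResExpression:
    """Naive super-resolution baseline: spread each spot evenly over its disc.

    Every superpixel whose center lies inside a spot's disc receives an equal
    share of that spot's expression; superpixels covered by no spot stay zero.
    Useful as the reference any learned model must beat.
    """
    xg, yg = grid.superpixel_centers_um()
    centers = np.stack([xg.ravel(), yg.ravel()], axis=1)
    d = cdist(spot_expr.layout.centers_um, centers)
    member = d <= spot_expr.layout.radius_um
    n_cover = member.sum(axis=1)
    weights = np.divide(
        member.astype(float),
        n_cover[:, None],
        out=np.zeros_like(member, dtype=float),
        where=n_cover[:, None] > 0,
    )
    flat = weights.T @ spot_expr.counts
    values = flat.reshape(grid.n_rows, grid.n_cols, -1)
    mask = member.any(axis=0).reshape(grid.n_rows, grid.n_cols)
    return HighResExpression(
        values=values, mask=mask, grid=grid, gene_names=spot_expr.gene_names
    )


def select_hvg(spot_expr: SpotExpression, n: int = 1000) -> SpotExpression:
    """Restrict to the top-n highly variable genes.

    Genes are ranked by the variance of library-size-normalized, log1p
    transformed counts (each spot scaled to the median library size), with ties
    broken by gene-name lexicographic order. The returned matrix keeps the
    original column order of the selected genes.
    """
    counts = spot_expr.counts
    if n > counts.shape[1]:
        raise ValueError(
            f"cannot select {n} genes from {counts.shape[1]} available"
        )
    lib = counts.sum(axis=1)
    target = np.median(lib[lib > 0]) if np.any(lib > 0) else 1.0
    scale = np.divide(target, lib, out=np.zeros_like(lib), where=lib > 0)
    logn = np.log1p(counts * scale[:, None])
    disp = logn.var(axis=0)
    order = sorted(
        range(counts.shape[1]), key=lambda k: (-disp[k], spot_expr.gene_names[k])
    )
    chosen = sorted(order[:n])  # keep original column order
    return SpotExpression(
        counts=counts[:, chosen],
        gene_names=tuple(spot_expr.gene_names[k] for k in chosen),
        layout=spot_expr.layout,
    )
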