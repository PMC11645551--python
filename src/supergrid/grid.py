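"""Grid geometry and in-memory containers for spot- and superpixel-level data.

Coordinate conventions used throughout the package:

* physical units are micrometres (µm); the origin sits at the top-left of the
  rescaled histology image, x grows rightward (columns), y grows downward (rows);
* superpixel ``(m, n)`` means (row, col), 0-based, covering the half-open square
  ``[m*s, (m+1)*s) x [n*s, (n+1)*s)`` µm with ``s`` the superpixel side length;
* one superpixel corresponds to one 16x16 pixel patch at 0.5 µm/px (8 µm side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SuperpixelGrid",
    "SpotLayout",
    "SpotExpression",
    "CellTable",
    "HighResExpression",
    "make_spot_layout",
]


@dataclass(frozen=True)
class SuperpixelGrid:
    """Regular square grid of superpixels in physical coordinates.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions in superpixels.
    superpixel_um : float
        Physical side length of one superpixel (default 8 µm, roughly one cell).
    pixel_size_um : float
        Physical size of one image pixel after rescaling (default 0.5 µm), so the
        default per-superpixel pixel span is 16.
    origin_um : tuple of float
        (x, y) physical offset of the grid's top-left corner.
    """

    n_rows: int
    n_cols: int
    superpixel_um: float = 8.0
    pixel_size_um: float = 0.5
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.superpixel_um <= 0:
            raise ValueError("superpixel_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        span = self.superpixel_um / self.pixel_size_um
        if abs(span - round(span)) > 1e-9 or round(span) < 1:
            raise ValueError(
                f"superpixel_um / pixel_size_um = {span} must be a positive integer"
            )

    @property
    def pixel_span(self) -> int:
        """Number of image pixels per superpixel side (16 at the defaults)."""
        return round(self.superpixel_um / self.pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the grid in µm."""
        return (self.n_cols * self.superpixel_um, self.n_rows * self.superpixel_um)

    def superpixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays, each of shape (n_rows, n_cols)."""
        ox, oy = self.origin_um
        s = self.superpixel_um
        ys = oy + (np.arange(self.n_rows) + 0.5) * s
        xs = ox + (np.arange(self.n_cols) + 0.5) * s
        xg, yg = np.meshgrid(xs, ys)
        return xg, yg

    def superpixel_of(self, x_um: float, y_um: float) -> tuple[int, int]:
        """Row/col index of the superpixel containing a physical point."""
        ox, oy = self.origin_um
        m = int(math.floor((y_um - oy) / self.superpixel_um))
        n = int(math.floor((x_um - ox) / self.superpixel_um))
        return m, n

    def bbox_um(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        ox, oy = self.origin_um
        w, h = self.extent_um
        return (ox, oy, ox + w, oy + h)


@dataclass(frozen=True)
class SpotLayout:
    """Circular capture-spot layout (Visium-style).

    ``centers_um`` is an (S, 2) array of (x, y) spot centers. The default
    geometry is the Visium one: 55 µm diameter, 100 µm center-to-center pitch.
    """

    centers_um: np.ndarray
    diameter_um: float = 55.0
    pitch_um: float = 100.0
    lattice: str = "explicit"

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers_um, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValueError("centers_um must be an (S, 2) array")
        object.__setattr__(self, "centers_um", centers)
        if self.diameter_um <= 0 or self.pitch_um <= 0:
            raise ValueError("diameter_um and pitch_um must be positive")
        if self.diameter_um > self.pitch_um + 1e-9:
            raise ValueError("spot diameter must not exceed pitch")
        if self.lattice not in ("hex", "square", "explicit"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if len(centers) > 1:
            # pairwise distinctness; S stays small enough for the quadratic check
            d2 = np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if np.min(d2) <= 1e-12:
                raise ValueError("spot centers must be pairwise distinct")

    @property
    def n_spots(self) -> int:
        return len(self.centers_um)

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


@dataclass(frozen=True)
class SpotExpression:
    """Spot-level expression: a spots x genes count matrix tied to a layout."""

    counts: np.ndarray
    gene_names: tuple[str, ...]
    layout: SpotLayout

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        if counts.shape[0] != self.layout.n_spots:
            raise ValueError(
                f"counts has {counts.shape[0]} rows but layout has "
                f"{self.layout.n_spots} spots"
            )
        if counts.shape[1] != len(self.gene_names):
            raise ValueError(
                f"counts has {counts.shape[1]} columns but {len(self.gene_names)} "
                "gene names were given"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


@dataclass(frozen=True)
class CellTable:
    """Per-cell expression with centroid/area geometry (Xenium-like export).

    ``footprints`` optionally carries per-cell axis-aligned boxes
    (xmin, ymin, xmax, ymax); when absent, a square of area ``areas_um2[k]``
    centered at the centroid is assumed for area-weighted partitioning.
    """

    cell_expression: np.ndarray
    centroids_um: np.ndarray
    areas_um2: np.ndarray
    gene_names: tuple[str, ...]
    footprints: object = None

    def __post_init__(self) -> None:
        expr = np.asarray(self.cell_expression, dtype=float)
        cent = np.asarray(self.centroids_um, dtype=float)
        areas = np.asarray(self.areas_um2, dtype=float)
        object.__setattr__(self, "cell_expression", expr)
        object.__setattr__(self, "centroids_um", cent)
        object.__setattr__(self, "areas_um2", areas)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        if expr.ndim != 2:
            raise ValueError("cell_expression must be 2-D (cells x genes)")
        n = expr.shape[0]
        if cent.shape != (n, 2):
            raise ValueError("centroids_um must be (cells, 2)")
        if areas.shape != (n,):
            raise ValueError("areas_um2 must be (cells,)")
        if expr.shape[1] != len(self.gene_names):
            raise ValueError("gene_names length must match expression columns")
        if expr.size and expr.min() < 0:
            raise ValueError("cell expression must be non-negative")
        if n and areas.min() <= 0:
            raise ValueError("cell areas must be strictly positive")
        if self.footprints is not None:
            fp = self.footprints
            if isinstance(fp, (list, tuple)) and fp and hasattr(fp[0], "area"):
                # shapely polygons
                if len(fp) != n:
                    raise ValueError("one footprint polygon per cell required")
                fa = np.array([p.area for p in fp])
                object.__setattr__(self, "footprints", tuple(fp))
            else:
                fp = np.asarray(fp, dtype=float)
                if fp.shape != (n, 4):
                    raise ValueError(
                        "footprints must be (cells, 4) boxes or shapely polygons"
                    )
                fa = (fp[:, 2] - fp[:, 0]) * (fp[:, 3] - fp[:, 1])
                object.__setattr__(self, "footprints", fp)
            rel = np.abs(fa - areas) / np.maximum(areas, 1e-300)
            if n and rel.max() > 1e-6:
                raise ValueError("footprint areas disagree with areas_um2")

    @property
    def n_cells(self) -> int:
        return self.cell_expression.shape[0]

    @property
    def has_polygon_footprints(self) -> bool:
        return isinstance(self.footprints, tuple)

    def footprint_boxes(self) -> np.ndarray:
        """Axis-aligned (xmin, ymin, xmax, ymax) bounds per cell.

        Explicit boxes are returned as-is; polygon footprints yield their
        bounding boxes (used for candidate-superpixel search); otherwise a
        square of the recorded area centered at the centroid is synthesized.
        """
        if self.has_polygon_footprints:
            return np.array([p.bounds for p in self.footprints])
        if self.footprints is not None:
            return self.footprints
        half = np.sqrt(self.areas_um2) / 2.0
        x, y = self.centroids_um[:, 0], self.centroids_um[:, 1]
        return np.stack([x - half, y - half, x + half, y + half], axis=1)


@dataclass(frozen=True)
class HighResExpression:
    """Superpixel-grid expression field with a tissue validity mask.

    ``values`` is (n_rows, n_cols, genes), non-negative, exactly zero outside
    ``mask``. This container is both the simulation ground truth and the model
    output.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: SuperpixelGrid
    gene_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        if values.ndim != 3:
            raise ValueError("values must be 3-D (rows x cols x genes)")
        if values.shape[:2] != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("values spatial shape must match the grid")
        if mask.shape != values.shape[:2]:
            raise ValueError("mask shape must match the grid")
        if values.shape[2] != len(self.gene_names):
            raise ValueError("gene_names length must match the gene axis")
        if values.size and values.min() < 0:
            raise ValueError("expression values must be non-negative")
        if values.size and np.any(values[~mask] != 0):
            raise ValueError("values outside the mask must be exactly zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def gene_map(self, gene: str) -> np.ndarray:
        """2-D expression field of a single gene."""
        try:
            k = self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None
        return self.values[:, :, k]


def _axis_positions(lo: float, hi: float, margin: float, step: float) -> np.ndarray:
    """Centered 1-D lattice positions in [lo+margin, hi+margin] at ``step``."""
    usable = (hi - lo) - 2.0 * margin
    if usable < -1e-9:
        return np.empty(0)
    n = int(math.floor(usable / step + 1e-9)) + 1
    start = lo + ((hi - lo) - (n - 1) * step) / 2.0
    return start + step * np.arange(n)


def make_spot_layout(
    bbox_um: Sequence[float],
    diameter_um: float = 55.0,
    pitch_um: float = 100.0,
    lattice: str = "hex",
) -> SpotLayout:
    """Tile a bounding box with capture spots on a hex or square lattice.

    The lattice is centered inside ``bbox_um = (xmin, ymin, xmax, ymax)``; no
    spot center is placed closer than one radius to the box edge, so every spot
    disc lies fully inside the box. Hex rows alternate an x offset of
    ``pitch/2`` with row spacing ``pitch * sqrt(3)/2``, which keeps every
    nearest-neighbour distance exactly at the pitch.

    Raises
    ------
    ValueError
        If the box is too small to hold a single spot ("bbox too small").
    """
    if lattice not in ("hex", "square"):
        raise ValueError("lattice must be 'hex' or 'square'")
    xmin, ymin, xmax, ymax = map(float, bbox_um)
    r = diameter_um / 2.0
    row_step = pitch_um * math.sqrt(3.0) / 2.0 if lattice == "hex" else pitch_um

    ys = _axis_positions(ymin, ymax, r, row_step)
    xs_base = _axis_positions(xmin, xmax, r, pitch_um)
    centers: list[tuple[float, float]] = []
    for i, y in enumerate(ys):
        if lattice == "hex" and i % 2 == 1:
            xs = xs_base + pitch_um / 2.0
            xs = xs[xs <= xmax - r + 1e-9]
        else:
            xs = xs_base
        centers.extend((float(x), float(y)) for x in xs)
    if not centers:
        raise ValueError("bbox too small for a single spot at this geometry")
    return SpotLayout(
        centers_um=np.asarray(centers, dtype=float),
        diameter_um=diameter_um,
        pitch_um=pitch_um,
        lattice=lattice,
    )
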