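"""Readers and writers for the package's on-disk formats.

Spot input follows the 10x conventions: a matrix-market triplet (``.mtx`` with
sibling ``barcodes.tsv``/``features.tsv``) or a spots x genes CSV, plus a
``tissue_positions``-dialect CSV (columns barcode, row, col, x_px, y_px) and a
JSON geometry block {pixel_size_um, spot_diameter_um, spot_pitch_um}. The
high-resolution container is HDF5 with datasets ``values``/``mask``/
``gene_names`` and the grid geometry in attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .grid import CellTable, HighResExpression, SpotExpression, SpotLayout, SuperpixelGrid

__all__ = [
    "read_spot_data",
    "write_spot_data",
    "read_cell_table",
    "write_highres",
    "read_highres",
    "write_feature_map",
    "read_feature_map",
]

_POSITION_COLUMNS = ["barcode", "row", "col", "x_px", "y_px"]


def _read_counts(counts_path: Path) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Return (spots x genes dense matrix, gene names, barcodes or None)."""
    if counts_path.suffix == ".mtx":
        mat = scipy.io.mmread(counts_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        features = counts_path.with_name("features.tsv")
        if not features.exists():
            features = counts_path.with_name("genes.tsv")
        genes = [
            line.split("\t")[0]
            for line in features.read_text().splitlines()
            if line.strip()
        ]
        barcodes_path = counts_path.with_name("barcodes.tsv")
        barcodes = [
            line.strip() for line in barcodes_path.read_text().splitlines() if line.strip()
        ]
        # 10x matrix-market stores genes x barcodes; transpose to spots x genes
        if mat.shape == (len(genes), len(barcodes)):
            mat = mat.T
        elif mat.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither (genes={len(genes)}, "
                f"barcodes={len(barcodes)}) nor its transpose"
            )
        return mat, genes, barcodes
    df = pd.read_csv(counts_path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns), [str(b) for b in df.index]


def read_spot_data(
    counts_path: str | Path,
    positions_path: str | Path,
    geometry: dict | str | Path,
) -> SpotExpression:
    """Load spot-level expression plus geometry into a :class:`SpotExpression`.

    ``geometry`` is a dict (or path to a JSON file) with keys ``pixel_size_um``,
    ``spot_diameter_um`` and ``spot_pitch_um``; spot centers are converted from
    full-resolution pixel coordinates to µm with ``pixel_size_um``.
    """
    counts_path = Path(counts_path)
    if isinstance(geometry, (str, Path)):
        geometry = json.loads(Path(geometry).read_text())
    counts, genes, barcodes = _read_counts(counts_path)
    pos = pd.read_csv(positions_path)
    missing = [c for c in _POSITION_COLUMNS if c not in pos.columns]
    if missing:
        raise ValueError(f"positions table lacks columns {missing}")
    if len(pos) != counts.shape[0]:
        raise ValueError(
            f"positions table has {len(pos)} barcodes but the counts matrix has "
            f"{counts.shape[0]} spots"
        )
    if barcodes is not None:
        pos = pos.set_index("barcode").loc[[str(b) for b in barcodes]].reset_index()
    px = float(geometry["pixel_size_um"])
    centers = np.stack(
        [pos["x_px"].to_numpy(dtype=float) * px, pos["y_px"].to_numpy(dtype=float) * px],
        axis=1,
    )
    layout = SpotLayout(
        centers_um=centers,
        diameter_um=float(geometry["spot_diameter_um"]),
        pitch_um=float(geometry["spot_pitch_um"]),
        lattice="explicit",
    )
    return SpotExpression(counts=counts, gene_names=tuple(genes), layout=layout)


def write_spot_data(
    out_dir: str | Path, spots: SpotExpression, pixel_size_um: float = 0.5
) -> None:
    """Write a SpotExpression as counts.csv + positions.csv + geometry.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    barcodes = [f"spot_{i:05d}" for i in range(spots.counts.shape[0])]
    pd.DataFrame(spots.counts, index=barcodes, columns=list(spots.gene_names)).to_csv(
        out / "counts.csv"
    )
    centers = spots.layout.centers_um
    pd.DataFrame(
        {
            "barcode": barcodes,
            "row": np.zeros(len(barcodes), dtype=int),
            "col": np.zeros(len(barcodes), dtype=int),
            "x_px": centers[:, 0] / pixel_size_um,
            "y_px": centers[:, 1] / pixel_size_um,
        }
    ).to_csv(out / "positions.csv", index=False)
    (out / "geometry.json").write_text(
        json.dumps(
            {
                "pixel_size_um": pixel_size_um,
                "spot_diameter_um": spots.layout.diameter_um,
                "spot_pitch_um": spots.layout.pitch_um,
            }
        )
    )


def read_cell_table(path: str | Path) -> CellTable:
    """Load a cell table CSV: columns cell_id, x_um, y_um, area_um2, then genes."""
    df = pd.read_csv(path)
    required = ["cell_id", "x_um", "y_um", "area_um2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cell table lacks columns {missing}")
    gene_cols = [c for c in df.columns if c not in required]
    return CellTable(
        cell_expression=df[gene_cols].to_numpy(dtype=float),
        centroids_um=df[["x_um", "y_um"]].to_numpy(dtype=float),
        areas_um2=df["area_um2"].to_numpy(dtype=float),
        gene_names=tuple(gene_cols),
    )


def write_cell_table(path: str | Path, cells: CellTable) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [f"cell_{k:06d}" for k in range(cells.n_cells)],
            "x_um": cells.centroids_um[:, 0],
            "y_um": cells.centroids_um[:, 1],
            "area_um2": cells.areas_um2,
        }
    )
    for j, g in enumerate(cells.gene_names):
        df[g] = cells.cell_expression[:, j]
    df.to_csv(path, index=False)


def write_highres(path: str | Path, highres: HighResExpression) -> None:
    """Write a HighResExpression to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=highres.values.astype(np.float32))
        f.create_dataset("mask", data=highres.mask.astype(np.uint8))
        f.create_dataset(
            "gene_names",
            data=np.array([g.encode("utf-8") for g in highres.gene_names]),
        )
        f.attrs["superpixel_um"] = highres.grid.superpixel_um
        f.attrs["pixel_size_um"] = highres.grid.pixel_size_um
        f.attrs["origin_um"] = list(highres.grid.origin_um)


def read_highres(path: str | Path) -> HighResExpression:
    with h5py.File(path, "r") as f:
        values = f["values"][...].astype(float)
        mask = f["mask"][...].astype(bool)
        genes = tuple(g.decode("utf-8") for g in f["gene_names"][...])
        grid = SuperpixelGrid(
            n_rows=values.shape[0],
            n_cols=values.shape[1],
            superpixel_um=float(f.attrs["superpixel_um"]),
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            origin_um=tuple(np.asarray(f.attrs["origin_um"], dtype=float)),
        )
    return HighResExpression(values=values, mask=mask, grid=grid, gene_names=genes)


def write_feature_map(path: str | Path, fmap) -> None:
    """Cache a MultimodalFeatureMap (channels + roles + mask + grid) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("channels", data=fmap.channels.astype(np.float32))
        f.create_dataset(
            "channel_roles",
            data=np.array([r.encode("utf-8") for r in fmap.channel_roles]),
        )
        f.create_dataset("mask", data=fmap.mask.astype(np.uint8))
        f.attrs["superpixel_um"] = fmap.grid.superpixel_um
        f.attrs["pixel_size_um"] = fmap.grid.pixel_size_um
        f.attrs["origin_um"] = list(fmap.grid.origin_um)


def read_feature_map(path: str | Path):
    from .features import MultimodalFeatureMap

    with h5py.File(path, "r") as f:
        channels = f["channels"][...].astype(float)
        roles = tuple(r.decode("utf-8") for r in f["channel_roles"][...])
        mask = f["mask"][...].astype(bool)
        grid = SuperpixelGrid(
            n_rows=channels.shape[1],
            n_cols=channels.shape[2],
            superpixel_um=float(f.attrs["superpixel_um"]),
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            origin_um=tuple(np.asarray(f.attrs["origin_um"], dtype=float)),
        )
    return MultimodalFeatureMap(channels=channels, channel_roles=roles, grid=grid, mask=mask)
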