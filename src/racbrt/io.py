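"""Cell-table and raster serialization.

The cell table is the pipeline's interchange format: one CSV row per
unmasked cell (``cell_id,row,col,x_km,y_km,...``), missing values as empty
fields, unknown columns preserved. Rasters are written as single-band
float32 TIFFs (row 0 = north, NaN nodata) with an ESRI world-file sidecar
(.tfw) carrying the planar-km affine transform.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

MANDATORY = ("cell_id", "row", "col")

__all__ = ["read_cell_table", "write_cell_table", "export_raster", "read_raster"]


def write_cell_table(table: pd.DataFrame, path) -> Path:
    """Write a cell_id-indexed (or cell_id-columned) table to CSV."""
    path = Path(path)
    out = table.reset_index() if table.index.name == "cell_id" else table.copy()
    missing = [c for c in MANDATORY if c not in out.columns]
    if missing:
        raise ValueError(f"cell table lacks mandatory columns: {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table CSV; returns a cell_id-indexed DataFrame."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in MANDATORY if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if table["cell_id"].duplicated().any():
        dupes = table.loc[table["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"{path}: duplicate cell_id values {dupes[:5]}")
    if len(table) == 0:
        warnings.warn(f"{path}: empty cell table", stacklevel=2)
    return table.set_index("cell_id")


def export_raster(grid, values: pd.Series, path) -> Path:
    """Write a cell_id-indexed series as a single-band float32 TIFF.

    Masked/absent cells become NaN. A .tfw world file records the km-scale
    affine (north-up, pixel size = cell size).
    """
    path = Path(path)
    known = values.index.difference(grid.cells()["cell_id"])
    if len(known):
        raise ValueError(f"values reference cells outside the grid: {list(known)[:5]}")
    plane = grid.to_array(values).astype(np.float32)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, plane)
    s = grid.cell_size_km
    # world file: x-scale, rot, rot, y-scale (negative: north-up), x/y of
    # the centre of the upper-left pixel
    world = [s, 0.0, 0.0, -s, s / 2, grid.n_rows * s - s / 2]
    path.with_suffix(".tfw").write_text("\n".join(f"{v:.10g}" for v in world) + "\n")
    return path


def read_raster(path) -> np.ndarray:
    return tifffile.imread(Path(path))
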