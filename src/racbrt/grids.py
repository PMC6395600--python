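"""Regular analysis lattices.

Every stage of the pipeline works on a :class:`CellGrid`: a north-up regular
lattice of square cells identified by 0-based (row, col) indices, row 0 being
the northernmost. Cell ids are ``row * n_cols + col`` and are stable under
masking, so tables indexed by ``cell_id`` stay joinable across grids derived
from one another (e.g. a 10-km survey grid and its 5-km refinement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellGrid",
    "generate_grid",
    "portugal_like_mask",
    "knight_move_select",
    "refine_grid",
]


@dataclass(frozen=True)
class CellGrid:
    """A masked regular lattice of square cells.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; row 0 is the northernmost row.
    cell_size_km
        Side length of a cell in km (5 or 10 in the study design).
    mask
        Boolean array of shape ``(n_rows, n_cols)``; True marks cells inside
        the study region. Masked-out cells carry no covariates downstream.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("mask shape does not match grid dimensions")
        object.__setattr__(self, "mask", mask)

    @property
    def n_cells(self) -> int:
        """Number of unmasked cells."""
        return int(self.mask.sum())

    def cell_id(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def row_col(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cells(self) -> pd.DataFrame:
        """Table of unmasked cells: cell_id, row, col, centroid x/y in km."""
        rows, cols = np.nonzero(self.mask)
        return pd.DataFrame(
            {
                "cell_id": self.cell_id(rows, cols),
                "row": rows,
                "col": cols,
                "x_km": (cols + 0.5) * self.cell_size_km,
                "y_km": (rows + 0.5) * self.cell_size_km,
            }
        )

    def to_array(self, values: pd.Series, fill=np.nan) -> np.ndarray:
        """Scatter a cell_id-indexed series onto the (n_rows, n_cols) plane."""
        out = np.full((self.n_rows, self.n_cols), fill, dtype=float)
        r, c = self.row_col(values.index.to_numpy())
        out[r, c] = values.to_numpy(dtype=float)
        return out


def generate_grid(n_rows: int, n_cols: int, cell_size_km: float, mask_spec=None) -> CellGrid:
    """Build a :class:`CellGrid`, applying an optional mask.

    ``mask_spec`` may be None (all cells inside), a boolean array, or a
    callable ``(n_rows, n_cols) -> bool array``.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    if mask_spec is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    elif callable(mask_spec):
        mask = np.asarray(mask_spec(n_rows, n_cols), dtype=bool)
    else:
        mask = np.asarray(mask_spec, dtype=bool)
    return CellGrid(n_rows, n_cols, float(cell_size_km), mask)


def portugal_like_mask(n_rows: int = 33, n_cols: int = 30) -> np.ndarray:
    """Synthetic stand-in for the 987-cell national 10-km grid.

    A full 33x30 lattice minus three southeastern corner cells leaves exactly
    987 cells -- the cell count of the study's mainland grid. The shape is
    deliberately schematic; no real geography is emulated.
    """
    mask = np.ones((n_rows, n_cols), dtype=bool)
    drop = min(3, n_rows * n_cols - 1)
    r, c = n_rows - 1, n_cols - 1
    for k in range(drop):
        mask[r, c - k] = False
    return mask


def knight_move_select(
    grid: CellGrid,
    start_corner: str = "NW",
    offset: int = 0,
    target_count: int | None = None,
) -> np.ndarray:
    """Regularly spaced cell selection following chess-knight displacement.

    Repeated knight moves from a corner close over the lattice
    ``{(r, c): (2r + c) mod 5 == offset}``, which selects ~1/5 of cells in a
    regular pattern. ``start_corner`` (NW/NE/SW/SE) fixes which corner the
    pattern is anchored at by mirroring indices. Returns sorted cell ids.

    If ``target_count`` is given and smaller than the pattern, the first
    ``target_count`` cells in reading order from the start corner are kept.
    """
    if grid.n_cells == 0:
        raise ValueError("grid has no unmasked cells")
    if target_count is not None and target_count > grid.n_cells:
        raise ValueError(
            f"target_count {target_count} exceeds unmasked cell count {grid.n_cells}"
        )
    corner = start_corner.upper()
    if corner not in {"NW", "NE", "SW", "SE"}:
        raise ValueError(f"unknown start corner {start_corner!r}")
    rows, cols = np.nonzero(grid.mask)
    r = rows if corner[0] == "N" else grid.n_rows - 1 - rows
    c = cols if corner[1] == "W" else grid.n_cols - 1 - cols
    keep = (2 * r + c) % 5 == offset % 5
    sel_rows, sel_cols = rows[keep], cols[keep]
    # reading order from the start corner for deterministic truncation
    order = np.lexsort((c[keep], r[keep]))
    ids = grid.cell_id(sel_rows, sel_cols)[order]
    if target_count is not None:
        ids = ids[:target_count]
    return np.sort(ids)


def refine_grid(grid: CellGrid, factor: int = 2) -> CellGrid:
    """Subdivide each cell into ``factor x factor`` subcells (10 km -> 5 km)."""
    mask = np.kron(grid.mask, np.ones((factor, factor), dtype=bool))
    return CellGrid(
        grid.n_rows * factor,
        grid.n_cols * factor,
        grid.cell_size_km / factor,
        mask,
    )
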